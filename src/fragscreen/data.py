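"""Published fragment-screen reference tables for the S100A1/S100B pair.

These are consumed as inputs (e.g. by the chemical-property summary);
nothing here is computed by this package.  Polar surface areas are the
published Cactvs values in Å^2.
"""

from __future__ import annotations

import pandas as pd

#: Chemical properties of the specificity-called fragments from the
#: 1000-compound HSQC screen of Ca2+-S100B vs Ca2+-S100A1.
S100_SCREEN_FRAGMENT_PROPERTIES = pd.DataFrame(
    [
        ("SPB05355", "S100B", 2, 2, 45.8),
        ("RJC03578", "S100B", 1, 3, 66.9),
        ("SEW01483", "S100B", 0, 3, 49.8),
        ("SEW01484", "S100B", 1, 3, 49.5),
        ("GK00671", "S100A1", 1, 4, 80.6),
        ("KM01765", "S100A1", 1, 4, 96.8),
        ("BTB10184", "S100B/S100A1", 2, 3, 65.8),
    ],
    columns=["compound", "specificity", "hbond_donors", "hbond_acceptors", "psa"],
)

#: Ligand grid free energies (kcal/mol) of the representative fragments'
#: selected binding poses on each target.
S100_SCREEN_LGFE = pd.DataFrame(
    [
        ("BTB10184", "S100B/S100A1", -6.52, -7.58),
        ("KM01765", "S100A1", -6.14, -5.43),
        ("SEW01483", "S100B", -5.97, -6.13),
    ],
    columns=["compound", "specificity", "lgfe_s100a1", "lgfe_s100b"],
)
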