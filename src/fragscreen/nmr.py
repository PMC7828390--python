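"""Scoring of fragment-induced spectral changes in 2D [1H,15N]-HSQC peak lists.

Each backbone amide gives one HSQC correlation.  Adding a binding fragment
perturbs correlations of residues near its site either by shifting them
(chemical shift perturbation, CSP; fast exchange) or by attenuating them
(line-broadening effect, LBE; intermediate exchange).  Both change classes
are tabulated as weak (score 1) or strong (score 2) per correlation; the
per-fragment total of these spectral-change scores, together with an
aggregation filter (broadening across most of the spectrum), drives the
binder / non-binder / specificity call when two homologous targets are
screened side by side.

The combined-shift metric is

    CSP = sqrt( 1/2 * [ dH^2 + (0.14 * dN)^2 ] )   [ppm]

with the 15N scale factor and the CSP/LBE class bounds exposed in
:class:`ScoringParameters`.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger(__name__)

PeakKey = tuple[str, int]

CSP_CLASSES = ("none", "weak", "strong")

#: Specificity calls for a fragment screened against two homologs A and B.
CALL_A_SPECIFIC = "A-specific"
CALL_B_SPECIFIC = "B-specific"
CALL_DUAL = "dual"
CALL_NON_BINDER = "non-binder"
CALL_AGGREGATOR = "aggregator"
SPECIFICITY_CALLS = (
    CALL_A_SPECIFIC,
    CALL_B_SPECIFIC,
    CALL_DUAL,
    CALL_NON_BINDER,
    CALL_AGGREGATOR,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakAssignment:
    """One assigned backbone HN correlation."""

    residue_index: int
    residue_name: str
    chain_id: str
    delta_H: float  # ppm
    delta_N: float  # ppm
    intensity: float | None = None  # arbitrary units; None if not measured

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be a positive integer")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if not (-2.0 <= self.delta_H <= 15.0):
            log.warning(
                "1H shift %.3f ppm for %s%d outside typical [-2, 15] ppm",
                self.delta_H, self.chain_id, self.residue_index,
            )
        if not (90.0 <= self.delta_N <= 140.0):
            log.warning(
                "15N shift %.2f ppm for %s%d outside typical backbone-amide "
                "[90, 140] ppm",
                self.delta_N, self.chain_id, self.residue_index,
            )

    @property
    def key(self) -> PeakKey:
        return (self.chain_id, self.residue_index)


@dataclass
class PeakList:
    """Assigned peaks of one spectrum, keyed by (chain_id, residue_index)."""

    peaks: dict[PeakKey, PeakAssignment]
    label: str  # "reference" or a fragment identifier

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("PeakList must contain at least one peak")

    @classmethod
    def from_assignments(cls, assignments, label: str) -> "PeakList":
        peaks: dict[PeakKey, PeakAssignment] = {}
        for pk in assignments:
            if pk.key in peaks:
                raise ValueError(f"duplicate assignment key {pk.key}")
            peaks[pk.key] = pk
        return cls(peaks=peaks, label=label)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class ScoringParameters:
    """Spectral-change classification thresholds and scores."""

    nitrogen_scale: float = 0.14    # 15N shift weight in the combined CSP
    csp_weak_low: float = 0.01      # ppm; weak CSP iff csp_weak_low < CSP < csp_strong
    csp_strong: float = 0.025       # ppm; strong CSP iff CSP >= csp_strong
    lbe_weak_frac: float = 0.40     # weak LBE iff decrease > lbe_weak_frac
    lbe_strong_frac: float = 0.90   # strong LBE iff decrease > lbe_strong_frac
    aggregation_frac: float = 0.30  # aggregator iff broadened fraction > this
    weak_score: int = 1
    strong_score: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.csp_weak_low < self.csp_strong):
            raise ValueError("require 0 < csp_weak_low < csp_strong")
        if not (0 < self.lbe_weak_frac < self.lbe_strong_frac <= 1):
            raise ValueError("require 0 < lbe_weak_frac < lbe_strong_frac <= 1")
        if not self.weak_score < self.strong_score:
            raise ValueError("require weak_score < strong_score")

    def class_score(self, cls: str) -> int:
        return {"none": 0, "weak": self.weak_score, "strong": self.strong_score}[cls]


@dataclass
class SpectralChangeRecord:
    """Classified change of one correlation between reference and perturbed."""

    key: PeakKey
    csp: float                     # ppm; 0 when unmeasurable
    intensity_decrease: float      # fraction in [0, 1]; missing peak -> 1.0
    csp_class: str
    lbe_class: str
    score: int

    def __post_init__(self) -> None:
        if self.csp < 0:
            raise ValueError("csp must be non-negative")
        if self.csp_class not in CSP_CLASSES or self.lbe_class not in CSP_CLASSES:
            raise ValueError("classes must be none|weak|strong")


@dataclass
class FragmentScreenResult:
    """Per-fragment, per-protein tabulation of spectral-change scores."""

    fragment_id: str
    protein_id: str
    records: list[SpectralChangeRecord]
    total_score: int
    perturbed_fraction: float  # fraction of reference correlations with an LBE
    aggregator: bool

    def __post_init__(self) -> None:
        expected = sum(r.score for r in self.records)
        if expected != self.total_score:
            raise ValueError("total_score must equal the sum of record scores")
        if not (0.0 <= self.perturbed_fraction <= 1.0):
            raise ValueError("perturbed_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    "chain_id",
    "residue_index",
    "residue_name",
    "delta_N_ppm",
    "delta_H_ppm",
    "intensity",
)

#: Sparky-style assignment, e.g. "A9N-H" (residue letter(s), number, N-H).
_SPARKY_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)N-?H$")


class PeakListFormatError(ValueError):
    pass


def read_peak_list(path: str | Path, format: str = "csv", label: str | None = None) -> PeakList:
    """Read a peak list from delimited text.

    ``csv`` dialect: header ``chain_id,residue_index,residue_name,
    delta_N_ppm,delta_H_ppm,intensity``.  ``sparky`` dialect: whitespace
    columns ``assignment w1 w2 height`` with w1 = 15N ppm, w2 = 1H ppm and
    assignments like ``A9N-H`` (chain defaults to "A").
    """
    path = Path(path)
    if label is None:
        label = path.stem
    if format == "csv":
        return _read_csv_peaks(path, label)
    if format == "sparky":
        return _read_sparky_peaks(path, label)
    raise ValueError(f"unknown peak-list format {format!r}")


def _read_csv_peaks(path: Path, label: str) -> PeakList:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header and c != "intensity"]
        if missing:
            raise PeakListFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        has_intensity = "intensity" in header
        assignments = []
        for row in reader:
            intensity = None
            if has_intensity and row["intensity"] not in (None, ""):
                intensity = float(row["intensity"])
            assignments.append(
                PeakAssignment(
                    residue_index=int(row["residue_index"]),
                    residue_name=row["residue_name"],
                    chain_id=row["chain_id"],
                    delta_H=float(row["delta_H_ppm"]),
                    delta_N=float(row["delta_N_ppm"]),
                    intensity=intensity,
                )
            )
    return PeakList.from_assignments(assignments, label=label)


def _read_sparky_peaks(path: Path, label: str, chain_id: str = "A") -> PeakList:
    assignments = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        toks = line.split()
        if len(toks) < 3:
            raise PeakListFormatError(
                f"{path}:{lineno}: expected 'assignment w1 w2 [height]'"
            )
        m = _SPARKY_ASSIGNMENT_RE.match(toks[0])
        if m is None:
            raise PeakListFormatError(
                f"{path}:{lineno}: unparsable assignment {toks[0]!r}"
            )
        assignments.append(
            PeakAssignment(
                residue_index=int(m.group(2)),
                residue_name=m.group(1),
                chain_id=chain_id,
                delta_N=float(toks[1]),
                delta_H=float(toks[2]),
                intensity=float(toks[3]) if len(toks) > 3 else None,
            )
        )
    return PeakList.from_assignments(assignments, label=label)


def write_peak_list_csv(peaks: PeakList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for key in sorted(peaks.peaks):
            pk = peaks.peaks[key]
            writer.writerow(
                [
                    pk.chain_id,
                    pk.residue_index,
                    pk.residue_name,
                    f"{pk.delta_N:.4f}",
                    f"{pk.delta_H:.4f}",
                    "" if pk.intensity is None else f"{pk.intensity:.6g}",
                ]
            )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def compute_csp(
    ref: PeakAssignment,
    bound: PeakAssignment,
    params: ScoringParameters = ScoringParameters(),
) -> float:
    """Combined 1H/15N chemical shift perturbation, ppm.

    Symmetric in ref/bound and in the sign of either shift difference;
    reduces to |dH|/sqrt(2) when the 15N shift is unchanged.
    """
    if ref.key != bound.key:
        raise ValueError(f"assignment keys differ: {ref.key} vs {bound.key}")
    d_h = bound.delta_H - ref.delta_H
    d_n = bound.delta_N - ref.delta_N
    return math.sqrt(0.5 * (d_h**2 + (params.nitrogen_scale * d_n) ** 2))


def classify_csp(csp: float, params: ScoringParameters = ScoringParameters()) -> str:
    """Classify a CSP: weak iff csp_weak_low < CSP < csp_strong, strong iff
    CSP >= csp_strong, else none."""
    if csp < 0:
        raise ValueError("csp must be non-negative")
    if csp >= params.csp_strong:
        return "strong"
    if csp > params.csp_weak_low:
        return "weak"
    return "none"


def classify_lbe(
    intensity_ref: float,
    intensity_bound: float,
    params: ScoringParameters = ScoringParameters(),
) -> tuple[float, str]:
    """Fractional intensity decrease and its LBE class.

    Weak iff the decrease is > lbe_weak_frac (and <= lbe_strong_frac),
    strong iff > lbe_strong_frac; both bounds strict, so a decrease of
    exactly 90% is weak.  A vanished peak (intensity 0) is strong.
    """
    if intensity_ref <= 0:
        raise ValueError("intensity_ref must be positive")
    if intensity_bound < 0:
        raise ValueError("intensity_bound must be non-negative")
    decrease = max(0.0, 1.0 - intensity_bound / intensity_ref)
    if decrease > params.lbe_strong_frac:
        cls = "strong"
    elif decrease > params.lbe_weak_frac:
        cls = "weak"
    else:
        cls = "none"
    return decrease, cls


def score_fragment(
    reference: PeakList,
    perturbed: PeakList,
    params: ScoringParameters = ScoringParameters(),
    fragment_id: str | None = None,
    protein_id: str = "",
) -> FragmentScreenResult:
    """Tabulate per-correlation spectral-change scores for one fragment.

    Every reference correlation yields one record: matched peaks get a CSP
    and (when intensities are present) an LBE classification; reference
    peaks absent from the perturbed list count as fully broadened
    (decrease 1.0, strong LBE).  A correlation showing both a CSP and an
    LBE scores the larger of the two classes — both report the same
    physical binding event.  Peaks present only in the perturbed list
    cannot be an assigned perturbation and are ignored with a warning.
    """
    shared = set(reference.peaks) & set(perturbed.peaks)
    if not shared:
        raise ValueError(
            f"no shared assignment keys between {reference.label!r} and "
            f"{perturbed.label!r}"
        )
    extra = set(perturbed.peaks) - set(reference.peaks)
    if extra:
        log.warning(
            "%d peak(s) in perturbed list %r missing from the reference are "
            "ignored: %s",
            len(extra), perturbed.label, sorted(extra)[:5],
        )

    records: list[SpectralChangeRecord] = []
    for key in sorted(reference.peaks):
        ref_pk = reference.peaks[key]
        if key in perturbed.peaks:
            bnd_pk = perturbed.peaks[key]
            csp = compute_csp(ref_pk, bnd_pk, params)
            csp_class = classify_csp(csp, params)
            if ref_pk.intensity is None or bnd_pk.intensity is None:
                log.info("no intensity for %s; CSP-only scoring", key)
                decrease, lbe_class = 0.0, "none"
            else:
                decrease, lbe_class = classify_lbe(
                    ref_pk.intensity, bnd_pk.intensity, params
                )
        else:
            # Assigned correlation vanished: complete line broadening.
            csp, csp_class = 0.0, "none"
            decrease, lbe_class = 1.0, "strong"
        score = max(params.class_score(csp_class), params.class_score(lbe_class))
        records.append(
            SpectralChangeRecord(
                key=key,
                csp=csp,
                intensity_decrease=decrease,
                csp_class=csp_class,
                lbe_class=lbe_class,
                score=score,
            )
        )

    n_broadened = sum(1 for r in records if r.lbe_class != "none")
    perturbed_fraction = n_broadened / len(records)
    result = FragmentScreenResult(
        fragment_id=fragment_id if fragment_id is not None else perturbed.label,
        protein_id=protein_id,
        records=records,
        total_score=sum(r.score for r in records),
        perturbed_fraction=perturbed_fraction,
        aggregator=False,
    )
    result.aggregator = detect_aggregation(result, params)
    return result


def detect_aggregation(
    result: FragmentScreenResult, params: ScoringParameters = ScoringParameters()
) -> bool:
    """True iff line broadening hits strictly more than ``aggregation_frac``
    of the correlations — spectrum-wide broadening indicates fragment
    aggregation rather than site binding, and such data are discarded."""
    return result.perturbed_fraction > params.aggregation_frac


def classify_specificity(
    result_a: FragmentScreenResult,
    result_b: FragmentScreenResult,
    binder_threshold: int = 2,
) -> str:
    """Call a fragment's specificity from its side-by-side screens.

    Aggregation on either target disqualifies the fragment outright.
    Otherwise the fragment binds a target iff its spectral-change total
    meets ``binder_threshold`` (default 2: one strong or two weak
    perturbations); binding one target only is a specific call, both is
    dual, neither is a non-binder.
    """
    if result_a.fragment_id != result_b.fragment_id:
        raise ValueError(
            f"results refer to different fragments: "
            f"{result_a.fragment_id!r} vs {result_b.fragment_id!r}"
        )
    if result_a.aggregator or result_b.aggregator:
        return CALL_AGGREGATOR
    binds_a = result_a.total_score >= binder_threshold
    binds_b = result_b.total_score >= binder_threshold
    if binds_a and binds_b:
        return CALL_DUAL
    if binds_a:
        return CALL_A_SPECIFIC
    if binds_b:
        return CALL_B_SPECIFIC
    return CALL_NON_BINDER


def perturbed_residue_keys(
    result: FragmentScreenResult, min_class: str = "weak"
) -> set[PeakKey]:
    """Keys of correlations perturbed at or above ``min_class`` in either
    change category; used to anchor NMR-consistent pose selection."""
    order = {c: i for i, c in enumerate(CSP_CLASSES)}
    lo = order[min_class]
    return {
        r.key
        for r in result.records
        if order[r.csp_class] >= lo or order[r.lbe_class] >= lo
    }
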