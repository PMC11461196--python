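"""GWAS summary-statistics containers, IO, instrument selection and harmonization.

The exchange format is the de-facto tab-separated summary-statistics dialect
with canonical header ``SNP, chrom, pos, effect_allele, other_allele, eaf,
beta, se, pval, n``.  Column aliases ("EA", "NEA", "rsid", ...) are handled
through an explicit ``column_map``.  Coordinates are 1-based.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VariantAssociation",
    "InstrumentSelectionConfig",
    "HarmonizedInstrumentSet",
    "InstrumentSelection",
    "LDMatrix",
    "NoInstrumentsError",
    "read_sumstats",
    "write_sumstats",
    "f_statistic",
    "select_instruments",
    "clump_greedy",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the TSV dialect
CANONICAL_COLUMNS = (
    "SNP",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

MANDATORY_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta", "se", "pval")


class NoInstrumentsError(ValueError):
    """Raised when an MR leg is attempted with an empty instrument set."""


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator requires more SNPs than are available."""


@dataclass
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele effect (trait units for continuous
    traits, log-odds for binary outcomes); ``eaf`` is the effect-allele
    frequency.  ``pos`` is 1-based.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def validate(self) -> None:
        if not self.snp_id:
            raise ValueError("empty snp_id")
        if self.se is None or not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.pval is None or not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        ea = str(self.effect_allele).upper()
        oa = str(self.other_allele).upper()
        if not ea or not oa or ea == oa:
            raise ValueError(
                f"{self.snp_id}: effect and other allele must differ, got {ea}/{oa}"
            )

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1-eaf)``; None when eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        return _COMPLEMENT.get(ea) == oa


@dataclass
class InstrumentSelectionConfig:
    """Thresholds for instrument selection.

    Defaults: genome-wide suggestive threshold 1e-5 (5e-5 for SNP-poor
    exposures), MAF >= 0.01, greedy LD clumping at r^2 < 0.001 within a
    10,000 kb window, per-SNP F >= 10 (exclusion rule is strict F < 10),
    palindromic SNPs resolved by frequency outside the 0.42-0.58 window.
    """

    pval_threshold: float = 1e-5
    pval_threshold_sparse: float = 5e-5
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58)

    def __post_init__(self) -> None:
        for name in ("pval_threshold", "pval_threshold_sparse", "f_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.clump_r2 < 1):
            raise ValueError("clump_r2 must be in (0,1)")
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP exposure and outcome effects aligned to a common effect allele."""

    exposure_name: str
    outcome_name: str
    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    #: per-SNP disposition: (snp_id, tag, reason); dropped SNPs appear here only
    audit: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n = len(self.snp_ids)
        for arr in (self.beta_exp, self.se_exp, self.beta_out, self.se_out):
            if arr.shape != (n,):
                raise ValueError("parallel arrays must match snp_ids length")
        if n and (np.any(self.se_exp <= 0) or np.any(self.se_out <= 0)):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedInstrumentSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedInstrumentSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            snp_ids=[self.snp_ids[i] for i in keep],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
            audit=list(self.audit),
        )

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP Wald ratios and their first-order SEs."""
        return self.beta_out / self.beta_exp, self.se_out / np.abs(self.beta_exp)


@dataclass
class InstrumentSelection:
    """Outcome of :func:`select_instruments` with a per-stage audit."""

    instruments: list[VariantAssociation]
    status: str  # "ok" | "no-instruments"
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)


class LDMatrix:
    """Sparse symmetric pairwise r^2 lookup keyed by SNP id.

    Missing pairs are treated as r^2 = 0 (with a single warning), which
    matches the post-clumping assumption that unrecorded pairs are unlinked.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        self._warned = False
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key not in self._r2:
            if not self._warned:
                warnings.warn(
                    f"LD entry missing for pair ({a}, {b}); treating as r2=0",
                    stacklevel=2,
                )
                self._warned = True
            return 0.0
        return self._r2[key]

    @classmethod
    def from_table(cls, path: str | Path) -> "LDMatrix":
        """Read a 3-column TSV (snp_a, snp_b, r2), header optional."""
        ld = cls()
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                try:
                    r2 = float(row[2])
                except ValueError:
                    continue  # header row
                ld.set(row[0], row[1], r2)
        return ld

    @classmethod
    def from_square(cls, frame) -> "LDMatrix":
        """Build from a square pandas DataFrame of r^2 (index == columns)."""
        ld = cls()
        for a in frame.index:
            for b in frame.columns:
                if a != b:
                    ld.set(str(a), str(b), float(frame.loc[a, b]))
        return ld


# ---------------------------------------------------------------------------
# IO


def _coerce_row(raw: Mapping[str, str]) -> VariantAssociation:
    def _opt_float(key):
        v = raw.get(key)
        if v is None or v == "" or v == "NA":
            return None
        return float(v)

    def _opt_int(key):
        v = raw.get(key)
        if v is None or v == "" or v == "NA":
            return None
        return int(float(v))

    rec = VariantAssociation(
        snp_id=str(raw["SNP"]),
        effect_allele=str(raw["effect_allele"]).upper(),
        other_allele=str(raw["other_allele"]).upper(),
        beta=float(raw["beta"]),
        se=float(raw["se"]),
        pval=float(raw["pval"]),
        eaf=_opt_float("eaf"),
        chrom=str(raw["chrom"]) if raw.get("chrom") not in (None, "", "NA") else None,
        pos=_opt_int("pos"),
        n=_opt_int("n"),
    )
    rec.validate()
    return rec


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[VariantAssociation]:
    """Read a tab- or comma-separated summary-statistics table.

    Parameters
    ----------
    column_map:
        Mapping of file column names to canonical names, e.g.
        ``{"rsid": "SNP", "EA": "effect_allele"}``.
    strict:
        When True, any malformed row aborts with a ValueError naming the
        line; when False, malformed rows are skipped with a warning.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        remap = dict(column_map or {})
        canon_header = [remap.get(c, c) for c in header]
        missing = [c for c in MANDATORY_COLUMNS if c not in canon_header]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory columns {missing}; found {header}"
            )
        records: list[VariantAssociation] = []
        for lineno, row in enumerate(reader, start=2):
            raw = {remap.get(k, k): v for k, v in row.items()}
            try:
                records.append(_coerce_row(raw))
            except (ValueError, KeyError, TypeError) as exc:
                msg = f"{path}:{lineno}: {exc}"
                if strict:
                    raise ValueError(msg) from exc
                warnings.warn(f"skipping malformed row -- {msg}", stacklevel=2)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_sumstats(records: Iterable[VariantAssociation], path: str | Path) -> None:
    """Write records as a canonical TSV; round-trips through read_sumstats."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.snp_id,
                    _fmt(r.chrom),
                    _fmt(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pval),
                    _fmt(r.n),
                ]
            )


# ---------------------------------------------------------------------------
# selection


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F statistic, (beta/se)^2."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def clump_greedy(
    records: Sequence[VariantAssociation],
    ld: LDMatrix | Mapping[tuple[str, str], float] | None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping.

    Repeatedly keep the remaining record with the smallest p-value (ties by
    snp_id) and drop every other remaining record on the same chromosome
    within ``window_kb`` of it with r^2 >= ``r2_threshold``.  Records with
    missing positions are treated as within-window (conservative).  Output is
    sorted by (chrom, pos, snp_id).
    """
    if ld is None:
        ld = LDMatrix()
    elif isinstance(ld, Mapping):
        ld = LDMatrix(ld)
    remaining = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[VariantAssociation] = []
    window_bp = window_kb * 1000
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for r in remaining:
            same_chrom = (
                index.chrom is None or r.chrom is None or index.chrom == r.chrom
            )
            in_window = (
                index.pos is None
                or r.pos is None
                or abs(index.pos - r.pos) <= window_bp
            )
            if same_chrom and in_window and ld.r2(index.snp_id, r.snp_id) >= r2_threshold:
                continue  # clumped away
            survivors.append(r)
        remaining = survivors
    return sorted(
        kept, key=lambda r: (r.chrom or "", r.pos if r.pos is not None else -1, r.snp_id)
    )


def select_instruments(
    records: Sequence[VariantAssociation],
    cfg: InstrumentSelectionConfig | None = None,
    ld: LDMatrix | Mapping[tuple[str, str], float] | None = None,
    sparse: bool = False,
) -> InstrumentSelection:
    """Select genetic instruments: pval -> MAF -> F -> LD clump, in that order.

    ``sparse=True`` applies the relaxed p-value threshold intended for
    SNP-poor exposures.  Records without an allele frequency pass the MAF
    filter with a warning.  The exclusion rule for weak instruments is strict
    F < f_min (a SNP with F exactly at the threshold is retained).
    """
    cfg = cfg or InstrumentSelectionConfig()
    warns: list[str] = []
    threshold = cfg.pval_threshold_sparse if sparse else cfg.pval_threshold
    counts = {"input": len(records)}

    stage = [r for r in records if r.pval < threshold]
    counts["after_pval"] = len(stage)

    kept = []
    missing_eaf = 0
    for r in stage:
        if r.maf is None:
            missing_eaf += 1
            kept.append(r)
        elif r.maf >= cfg.maf_min:
            kept.append(r)
    if missing_eaf:
        warns.append(f"{missing_eaf} records lack eaf; passed MAF filter unchecked")
    stage = kept
    counts["after_maf"] = len(stage)

    stage = [r for r in stage if f_statistic(r.beta, r.se) >= cfg.f_min]
    counts["after_f"] = len(stage)

    if ld is not None:
        stage = clump_greedy(stage, ld, cfg.clump_r2, cfg.clump_window_kb)
    counts["after_clump"] = len(stage)

    status = "ok" if stage else "no-instruments"
    return InstrumentSelection(instruments=stage, status=status, counts=counts, warnings=warns)


# ---------------------------------------------------------------------------
# harmonization


def _complementable(*alleles: str) -> bool:
    return all(a in _COMPLEMENT for a in alleles)


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align outcome SNP effects to the exposure's effect alleles.

    Rules, per shared SNP: identical alleles in the same order are kept;
    swapped alleles negate the outcome beta (and mirror its frequency);
    alleles matching after strand complement are complemented first;
    palindromic (A/T, C/G) SNPs are oriented by allele-frequency agreement
    when both frequencies lie outside ``palindrome_eaf_window`` and dropped
    as ambiguous otherwise; anything else is dropped as incompatible.
    """
    lo, hi = palindrome_eaf_window
    out_by_id = {r.snp_id: r for r in outcome}
    snp_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    audit: list[tuple[str, str, str]] = []

    for e in exposure:
        o = out_by_id.get(e.snp_id)
        if o is None:
            continue
        ea, oa = e.effect_allele.upper(), e.other_allele.upper()
        oea, ooa = o.effect_allele.upper(), o.other_allele.upper()
        beta_out, eaf_out = o.beta, o.eaf
        tag = "kept-as-is"

        if {oea, ooa} == {ea, oa}:
            pass
        elif _complementable(ea, oa, oea, ooa) and {
            _complement(oea),
            _complement(ooa),
        } == {ea, oa}:
            oea, ooa = _complement(oea), _complement(ooa)
            tag = "strand-flipped"
        else:
            audit.append((e.snp_id, "dropped", "incompatible-alleles"))
            continue

        if (oea, ooa) != (ea, oa):
            # swapped order relative to the exposure coding
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
            tag = "outcome-flipped" if tag == "kept-as-is" else "strand-flipped"

        if e.is_palindromic():
            ambiguous = (
                e.eaf is None
                or eaf_out is None
                or lo <= e.eaf <= hi
                or lo <= eaf_out <= hi
            )
            if ambiguous:
                audit.append((e.snp_id, "dropped", "palindromic-ambiguous"))
                continue
            if (e.eaf < 0.5) != (eaf_out < 0.5):
                # frequencies disagree: the outcome is reported on the other strand
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                tag = "strand-flipped"

        snp_ids.append(e.snp_id)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(beta_out)
        sy.append(o.se)
        audit.append((e.snp_id, tag, ""))

    return HarmonizedInstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        snp_ids=snp_ids,
        beta_exp=np.array(bx, dtype=float),
        se_exp=np.array(sx, dtype=float),
        beta_out=np.array(by, dtype=float),
        se_out=np.array(sy, dtype=float),
        audit=audit,
    )
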