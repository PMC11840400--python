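"""Reading, writing and allele-harmonizing GWAS summary statistics.

Two-sample MR consumes per-variant association estimates from two
independent cohorts (instrument-exposure effects ``gamma`` and
instrument-outcome effects ``Gamma``).  Before any estimator runs, the
two sets must refer to the same effect allele for every variant; this
module owns that alignment step and the flat-file format the rest of
the package exchanges.

Files are UTF-8 tab-separated tables with a header row.  The canonical
column order is ``id, chrom, pos, effect_allele, other_allele, eaf,
beta, se, pval, n``; a ``dialect`` mapping lets foreign headers be read
without rewriting the file.  Missing effect-allele frequency is encoded
as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Variant",
    "AssociationRecord",
    "ReadResult",
    "HarmonizedSet",
    "ConfigurationError",
    "SummaryStatsParseError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """A summary-statistic file or dialect map is unusable as configured."""


class SummaryStatsParseError(ValueError):
    """A row could not be parsed at all (as opposed to failing an invariant)."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with its effect-allele frequency.

    ``eaf`` may be ``None`` when the source file did not report it.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValueError(f"{self.id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.id}: eaf {self.eaf} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, where strand cannot be resolved from alleles."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]

    def flipped(self) -> "Variant":
        """The same variant reported on the opposite effect allele."""
        return Variant(
            id=self.id, chrom=self.chrom, pos=self.pos,
            effect_allele=self.other_allele, other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's estimated effect on one trait.

    ``beta`` is per effect allele on the trait scale (mg/dL for a
    continuous glycaemic trait, log-odds for a binary event).
    """

    variant: Variant
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant.id}: non-positive SE")
        if self.n < 1:
            raise ValueError(f"{self.variant.id}: n < 1")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant.id}: pval outside (0, 1]")

    def flipped(self) -> "AssociationRecord":
        """Re-express the estimate on the opposite effect allele (sign flip)."""
        return AssociationRecord(
            variant=self.variant.flipped(),
            beta=-self.beta, se=self.se, pval=self.pval, n=self.n,
        )


@dataclass
class ReadResult:
    """Records parsed from a file plus the rows rejected with reasons.

    Iterating or indexing the result yields the valid records, so it can
    be used wherever a plain record list is expected.
    """

    records: list[AssociationRecord]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect pairs for J instruments.

    After harmonization every retained variant's outcome estimate refers
    to the same effect allele as its exposure estimate, so the per-variant
    vectors (gamma, Gamma) can be combined directly by the MR estimators.
    """

    exposure_records: list[AssociationRecord]
    outcome_records: list[AssociationRecord]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.exposure_records) != len(self.outcome_records):
            raise ValueError("exposure and outcome record lists differ in length")
        for e, o in zip(self.exposure_records, self.outcome_records):
            if e.variant.id != o.variant.id:
                raise ValueError(f"record order mismatch at {e.variant.id}")
            if e.variant.effect_allele != o.variant.effect_allele:
                raise ValueError(f"{e.variant.id}: effect alleles not aligned")

    def __len__(self) -> int:
        return len(self.exposure_records)

    @property
    def variants(self) -> list[Variant]:
        return [r.variant for r in self.exposure_records]

    @property
    def gamma(self):
        import numpy as np
        return np.array([r.beta for r in self.exposure_records])

    @property
    def sigma_gamma(self):
        import numpy as np
        return np.array([r.se for r in self.exposure_records])

    @property
    def Gamma_out(self):
        import numpy as np
        return np.array([r.beta for r in self.outcome_records])

    @property
    def sigma_Gamma(self):
        import numpy as np
        return np.array([r.se for r in self.outcome_records])


def _resolve_columns(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical column names to the file's actual headers."""
    mapping = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        mapping.update(dialect)
    missing = [canon for canon, actual in mapping.items() if actual not in columns]
    if missing:
        raise ConfigurationError(
            "missing required column(s): "
            + ", ".join(f"{m} (mapped to '{mapping[m]}')" for m in missing)
        )
    return mapping


def read_summary_stats(path: str | Path, dialect: Mapping[str, str] | None = None) -> ReadResult:
    """Read a TSV of summary statistics into :class:`AssociationRecord` rows.

    Rows that fail a domain invariant (non-positive SE, identical alleles,
    frequency outside [0, 1], ...) are collected in ``result.rejected`` with
    the variant id and reason rather than silently dropped.  Structural
    problems raise: a missing column raises :class:`ConfigurationError`
    naming the column, a non-numeric beta/se raises
    :class:`SummaryStatsParseError` with the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, dialect)

    canonical = df.rename(columns={actual: canon for canon, actual in cols.items()})
    result = ReadResult(records=[])
    for i, raw in enumerate(canonical[list(CANONICAL_COLUMNS)].to_dict("records")):
        line_no = i + 2  # 1-based, after the header
        vid = raw["id"]
        try:
            beta = float(raw["beta"])
            se = float(raw["se"])
        except ValueError as exc:
            raise SummaryStatsParseError(
                f"line {line_no}: non-numeric beta/se ({raw['beta']!r}, {raw['se']!r})"
            ) from exc
        try:
            eaf_raw = raw["eaf"]
            eaf = None if eaf_raw in ("NA", "", "nan") else float(eaf_raw)
            variant = Variant(
                id=vid, chrom=str(raw["chrom"]), pos=int(float(raw["pos"])),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                eaf=eaf,
            )
            record = AssociationRecord(
                variant=variant, beta=beta, se=se,
                pval=float(raw["pval"]), n=int(float(raw["n"])),
            )
        except ValueError as exc:
            result.rejected.append((vid, str(exc)))
            continue
        result.records.append(record)
    return result


def write_summary_stats(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write records as TSV in the canonical column order; missing eaf becomes NA."""
    rows = []
    for r in records:
        v = r.variant
        rows.append({
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "eaf": "NA" if v.eaf is None else repr(v.eaf),
            "beta": repr(r.beta), "se": repr(r.se),
            "pval": repr(r.pval), "n": r.n,
        })
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome estimates to the exposure effect alleles, variant by variant.

    Matching is by variant id only.  For each exposure variant:

    * no outcome record with that id -> dropped, reason ``"unmatched"``;
    * identical allele pair -> retained as-is;
    * swapped allele pair -> retained with the outcome beta sign flipped
      and its eaf complemented;
    * any other allele pair -> dropped, reason ``"allele-mismatch"``;
    * palindromic (A/T or C/G) variants whose exposure eaf lies inside
      the open window (0.5 - w, 0.5 + w), or is unknown, are dropped with
      reason ``"palindromic-ambiguous"`` — at intermediate frequency the
      allele pair cannot identify the strand, so the sign of the outcome
      effect would be a guess.

    No strand inference is attempted for non-palindromic variants: the
    reported alleles are authoritative.
    """
    if palindrome_eaf_window < 0:
        raise ValueError("palindrome_eaf_window must be >= 0")
    ids = [r.variant.id for r in exposure]
    if len(set(ids)) != len(ids):
        raise ValueError("exposure variant ids are not unique")
    outcome_by_id = {r.variant.id: r for r in outcome}

    kept_exp: list[AssociationRecord] = []
    kept_out: list[AssociationRecord] = []
    dropped: list[tuple[str, str]] = []
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    for exp in exposure:
        vid = exp.variant.id
        out = outcome_by_id.get(vid)
        if out is None:
            dropped.append((vid, "unmatched"))
            continue
        ev, ov = exp.variant, out.variant
        if (ev.effect_allele, ev.other_allele) == (ov.effect_allele, ov.other_allele):
            aligned = out
        elif (ev.effect_allele, ev.other_allele) == (ov.other_allele, ov.effect_allele):
            aligned = out.flipped()
        else:
            dropped.append((vid, "allele-mismatch"))
            continue
        if ev.is_palindromic:
            if ev.eaf is None or lo < ev.eaf < hi:
                dropped.append((vid, "palindromic-ambiguous"))
                continue
        kept_exp.append(exp)
        kept_out.append(aligned)

    return HarmonizedSet(exposure_records=kept_exp, outcome_records=kept_out, dropped=dropped)
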