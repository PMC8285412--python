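"""GWAS summary statistics: canonical variant identifiers, records and TSV I/O.

Variants are keyed by a canonical "cpaid" string ``chrom:pos:alleleA_alleleB``
with the two alleles in ASCII ascending order, so that the identifier is
independent of which allele a study happened to report as the effect allele.
Positions are 1-based (GRCh37/hg19 convention); chromosome labels are stored
without a ``chr`` prefix and X is stored as "23" so that plain tuple sorting
gives genomic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "VariantKey",
    "AssocRecord",
    "SumStats",
    "make_cpaid",
    "parse_cpaid",
    "normalize_chrom",
    "render_chrom",
    "harmonize",
    "read_sumstats",
    "write_sumstats",
    "HarmonizationError",
    "SumStatsFormatError",
]

_ALLELE_CHARS = frozenset("ACGT")


class HarmonizationError(ValueError):
    """Alleles of a record cannot be matched to the requested orientation."""


class SumStatsFormatError(ValueError):
    """A summary-statistics file violates the expected layout or invariants."""


def normalize_chrom(chrom: object) -> str:
    """Normalize a chromosome label: strip 'chr', map X->23, keep as string."""
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() == "X":
        s = "23"
    if not s:
        raise ValueError("empty chromosome label")
    return s


def render_chrom(chrom: str) -> str:
    """Render a stored chromosome label for output ('23' -> 'X')."""
    return "X" if str(chrom) == "23" else str(chrom)


def _check_allele(allele: str) -> str:
    if not isinstance(allele, str) or len(allele) == 0:
        raise ValueError(f"invalid allele {allele!r}: must be a non-empty string")
    a = allele.upper()
    if not set(a) <= _ALLELE_CHARS:
        raise ValueError(f"invalid allele {allele!r}: characters outside ACGT")
    return a


def make_cpaid(chrom: object, pos: int, allele1: str, allele2: str) -> str:
    """Build the canonical variant identifier ``chrom:pos:aX_aY``.

    The two alleles are sorted into ASCII ascending order, so the result does
    not depend on the order in which they are supplied.  Multi-character
    (indel) alleles follow the same rule.
    """
    a1, a2 = _check_allele(allele1), _check_allele(allele2)
    pos = int(pos)
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    lo, hi = sorted((a1, a2))
    return f"{normalize_chrom(chrom)}:{pos}:{lo}_{hi}"


def parse_cpaid(cpaid: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`make_cpaid`; returns (chrom, pos, alleleA, alleleB)."""
    try:
        chrom, pos, alleles = cpaid.split(":")
        a, b = alleles.split("_")
    except ValueError as exc:
        raise ValueError(f"malformed cpaid {cpaid!r}") from exc
    return chrom, int(pos), a, b


@dataclass(frozen=True, order=True)
class VariantKey:
    """A variant identified by chromosome, hg19 position and its allele pair."""

    chrom: str
    pos: int
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        a, b = sorted((_check_allele(self.alleleA), _check_allele(self.alleleB)))
        object.__setattr__(self, "alleleA", a)
        object.__setattr__(self, "alleleB", b)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def cpaid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.alleleA}_{self.alleleB}"

    @property
    def is_snp(self) -> bool:
        return len(self.alleleA) == 1 and len(self.alleleB) == 1

    @classmethod
    def from_cpaid(cls, cpaid: str) -> "VariantKey":
        chrom, pos, a, b = parse_cpaid(cpaid)
        return cls(chrom, pos, a, b)


def wald_p(beta: float, se: float) -> float:
    """Two-sided p-value from the normal Wald statistic beta/se."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * _st.norm.sf(abs(beta) / se))


@dataclass
class AssocRecord:
    """One variant's association statistics for one trait/stratum."""

    key: VariantKey
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    info: float | None = None
    trait: str = ""
    genotyped: bool = False

    def __post_init__(self) -> None:
        ea, oa = _check_allele(self.effect_allele), _check_allele(self.other_allele)
        self.effect_allele, self.other_allele = ea, oa
        if {ea, oa} != {self.key.alleleA, self.key.alleleB}:
            raise ValueError(
                f"effect/other alleles {{{ea},{oa}}} do not match key {self.key.cpaid}"
            )
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must be in (0,1), got {self.eaf} at {self.key.cpaid}")
        if self.se <= 0:
            raise ValueError(f"se must be > 0 at {self.key.cpaid}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must be in (0,1], got {self.p} at {self.key.cpaid}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def check_wald_consistency(self, rtol: float = 1e-3) -> bool:
        """Whether stored p agrees with the two-sided Wald p from beta/se."""
        expect = wald_p(self.beta, self.se)
        if expect == 0.0 or self.p == 0.0:
            return math.isclose(expect, self.p, rel_tol=rtol, abs_tol=1e-300)
        return abs(math.log(self.p) - math.log(expect)) <= -math.log1p(-rtol) * 10


def harmonize(record: AssocRecord, target_key: VariantKey,
              reference_effect: str | None = None) -> AssocRecord:
    """Orient ``record`` to a reference effect allele at the same variant.

    The reference effect allele defaults to the target key's alleleA.  When the
    record's effect allele differs, beta is negated and eaf replaced by
    ``1 - eaf``; se, p and n are untouched.  Harmonizing back restores the
    original record (involution).
    """
    ref = _check_allele(reference_effect) if reference_effect else target_key.alleleA
    if {record.key.alleleA, record.key.alleleB} != {target_key.alleleA, target_key.alleleB} \
            or (record.key.chrom, record.key.pos) != (target_key.chrom, target_key.pos):
        raise HarmonizationError(
            f"allele set mismatch: record {record.key.cpaid} vs target {target_key.cpaid}"
        )
    if ref not in (target_key.alleleA, target_key.alleleB):
        raise HarmonizationError(
            f"reference effect allele {ref} absent from {target_key.cpaid}"
        )
    if record.effect_allele == ref:
        return record
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=1.0 - record.eaf,
    )


# canonical column order for the internal tabular representation
_COLUMNS = ["cpaid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "info"]

DIALECTS: dict[str, Mapping[str, str]] = {
    "internal": {
        "cpaid": "cpaid", "ea": "ea", "oa": "oa", "eaf": "eaf",
        "beta": "beta", "se": "se", "p": "p", "n": "n", "info": "info",
    },
    "metal": {
        "cpaid": "MarkerName", "ea": "Allele1", "oa": "Allele2", "eaf": "Freq1",
        "beta": "Effect", "se": "StdErr", "p": "P-value", "n": "N",
    },
}


@dataclass
class SumStats:
    """An ordered collection of association records for one trait/stratum.

    Backed by a :class:`pandas.DataFrame` with the canonical columns
    ``cpaid, chrom, pos, ea, oa, eaf, beta, se, p, n, info`` sorted by
    (chrom, pos); cpaids are unique.  Extra columns are carried along as
    opaque payload.
    """

    df: pd.DataFrame
    trait: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _COLUMNS if c not in df.columns and c != "info"]
        if missing:
            raise SumStatsFormatError(f"missing mandatory columns: {missing}")
        if "info" not in df.columns:
            df["info"] = np.nan
        if df["cpaid"].duplicated().any():
            dups = df.loc[df["cpaid"].duplicated(), "cpaid"].head(3).tolist()
            raise SumStatsFormatError(f"duplicate cpaids, e.g. {dups}")
        df["chrom"] = df["chrom"].astype(str)
        chrom_num = pd.to_numeric(df["chrom"], errors="coerce").fillna(99)
        order = np.lexsort((df["pos"].to_numpy(), chrom_num.to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad = df.index[(df["eaf"] <= 0) | (df["eaf"] >= 1)]
        if len(bad):
            row = df.loc[bad[0]]
            raise SumStatsFormatError(
                f"eaf out of (0,1) at {row['cpaid']} (row {bad[0]}): {row['eaf']}"
            )
        bad = df.index[df["se"] <= 0]
        if len(bad):
            row = df.loc[bad[0]]
            raise SumStatsFormatError(f"se <= 0 at {row['cpaid']} (row {bad[0]})")
        bad = df.index[(df["p"] <= 0) | (df["p"] > 1)]
        if len(bad):
            row = df.loc[bad[0]]
            raise SumStatsFormatError(f"p out of (0,1] at {row['cpaid']} (row {bad[0]})")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[AssocRecord]:
        return iter(self.records())

    def records(self) -> list[AssocRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            info = getattr(row, "info", np.nan)
            out.append(AssocRecord(
                key=VariantKey.from_cpaid(row.cpaid),
                effect_allele=row.ea, other_allele=row.oa,
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                p=float(row.p), n=float(row.n),
                info=None if pd.isna(info) else float(info),
                trait=self.trait,
            ))
        return out

    @classmethod
    def from_records(cls, records: Iterable[AssocRecord], trait: str = "",
                     provenance: str = "") -> "SumStats":
        rows = []
        for r in records:
            rows.append({
                "cpaid": r.key.cpaid, "chrom": r.key.chrom, "pos": r.key.pos,
                "ea": r.effect_allele, "oa": r.other_allele, "eaf": r.eaf,
                "beta": r.beta, "se": r.se, "p": r.p, "n": r.n,
                "info": np.nan if r.info is None else r.info,
            })
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(df, trait=trait, provenance=provenance)

    def get(self, cpaid: str) -> AssocRecord:
        sub = self.df[self.df["cpaid"] == cpaid]
        if sub.empty:
            raise KeyError(cpaid)
        return SumStats(sub, trait=self.trait).records()[0]

    def subset(self, cpaids: Iterable[str]) -> "SumStats":
        want = set(cpaids)
        return SumStats(self.df[self.df["cpaid"].isin(want)].copy(),
                        trait=self.trait, provenance=self.provenance)


def read_sumstats(path, dialect: str = "internal", trait: str = "",
                  strict_snp: bool = False) -> SumStats:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps on-disk column names to the canonical schema; built-in
    dialects are ``internal`` and ``metal``.  Gzip is handled transparently
    (by extension).  Unknown columns are preserved as opaque extras.  With
    ``strict_snp`` set, indel records are rejected.
    """
    colmap = DIALECTS.get(dialect)
    if colmap is None:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    raw = pd.read_csv(path, sep="\t", dtype={colmap["cpaid"]: str})
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SumStatsFormatError(f"missing mandatory column(s) {missing} in {path}")
    inv = {src: dst for dst, src in colmap.items()}
    df = raw.rename(columns=inv)
    parsed = df["cpaid"].map(parse_cpaid)
    df["chrom"] = [normalize_chrom(t[0]) for t in parsed]
    df["pos"] = [t[1] for t in parsed]
    df["ea"] = df["ea"].str.upper()
    df["oa"] = df["oa"].str.upper()
    # re-canonicalize the identifier in case the source used raw chromosome labels
    df["cpaid"] = [make_cpaid(t[0], t[1], t[2], t[3]) for t in parsed]
    if strict_snp:
        bad = df[(df["ea"].str.len() > 1) | (df["oa"].str.len() > 1)]
        if not bad.empty:
            raise SumStatsFormatError(
                f"strict-SNP mode: indel alleles at {bad['cpaid'].head(3).tolist()}"
            )
    for i, row in df.iterrows():
        if {row["ea"], row["oa"]} != set(row["cpaid"].rsplit(":", 1)[1].split("_")):
            raise SumStatsFormatError(
                f"alleles {{{row['ea']},{row['oa']}}} do not match cpaid "
                f"{row['cpaid']} (row {i})"
            )
    ordered = [c for c in _COLUMNS if c in df.columns] \
        + [c for c in df.columns if c not in _COLUMNS]
    return SumStats(df[ordered], trait=trait, provenance=str(path))


def write_sumstats(stats: SumStats, path, dialect: str = "internal") -> None:
    """Write a SumStats table as TSV (numeric fields at 6 significant digits)."""
    colmap = DIALECTS.get(dialect)
    if colmap is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = stats.df.copy()
    out = pd.DataFrame()
    for dst, src in colmap.items():
        out[src] = df[dst]
    extras = [c for c in df.columns if c not in set(colmap) | {"chrom", "pos"}]
    for c in extras:
        out[c] = df[c]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
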