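"""Iterative definition of non-overlapping genome-wide-significant loci.

The algorithm repeatedly takes the smallest-p genome-wide-significant (GWS,
p < 5e-8) variant as a locus lead, finds the outermost GWS variants inside a
1-Mb window centred on it, extends the search by 500-kb steps beyond the
current outermost GWS variants until no further GWS variant is absorbed,
draws the locus borders at the outermost GWS positions +/- 250 kb (clamped at
1), removes everything inside the borders and repeats.  A locus is classified
as known when at least one of its GWS variants falls inside a previously
reported region; novelty is decided on GWS variants, not borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

__all__ = ["Locus", "define_loci", "classify_loci", "GWS_THRESHOLD"]

GWS_THRESHOLD = 5e-8


@dataclass
class Locus:
    """A genomic interval from the iterative locus algorithm (1-based, closed)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    lead_cpaid: str
    lead_pos: int
    lead_p: float
    gws_cpaids: list[str] = field(default_factory=list)
    gws_positions: list[int] = field(default_factory=list)
    novelty: str = "novel"

    @property
    def n_gws(self) -> int:
        return len(self.gws_cpaids)

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def define_loci(stats: SumStats, gws_threshold: float = GWS_THRESHOLD,
                half_window: int = 500_000, border: int = 250_000,
                step: int = 500_000) -> list[Locus]:
    """Partition GWS variants into disjoint loci; see module docstring.

    Ties in the minimum p are broken by (chrom, pos) ascending.  Returns an
    empty list when no variant is genome-wide significant.
    """
    df = stats.df[["cpaid", "chrom", "pos", "p"]]
    loci: list[Locus] = []
    per_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("pos").reset_index(drop=True) for c, g in df.groupby("chrom")
    }
    counter = 0
    while True:
        # global minimum-p GWS variant among remaining variants
        best = None
        for chrom in sorted(per_chrom, key=_chrom_sort_key):
            g = per_chrom[chrom]
            gws = g[g["p"] < gws_threshold]
            if gws.empty:
                continue
            # ties by (chrom, pos) ascending: stable because chroms scanned in order
            idx = gws["p"].idxmin()
            cand = gws.loc[idx]
            if best is None or cand["p"] < best["p"]:
                best = cand
        if best is None:
            break
        chrom = str(best["chrom"])
        g = per_chrom[chrom]
        pos = g["pos"].to_numpy()
        is_gws = (g["p"] < gws_threshold).to_numpy()
        lead_pos = int(best["pos"])

        # (2) outermost GWS variants within the 1-Mb window centred on the lead
        in_window = (pos >= lead_pos - half_window) & (pos <= lead_pos + half_window)
        sel = in_window & is_gws
        lo = int(pos[sel].min())
        hi = int(pos[sel].max())

        # (3) extend by `step` beyond the current outermost GWS variants
        while True:
            grew = False
            left = is_gws & (pos >= lo - step) & (pos < lo)
            if left.any():
                lo = int(pos[left].min())
                grew = True
            right = is_gws & (pos > hi) & (pos <= hi + step)
            if right.any():
                hi = int(pos[right].max())
                grew = True
            if not grew:
                break

        start = max(1, lo - border)
        end = hi + border
        member = sel | (is_gws & (pos >= lo) & (pos <= hi))
        members = g[member]
        counter += 1
        loci.append(Locus(
            locus_id=f"L{counter}", chrom=chrom, start=start, end=end,
            lead_cpaid=str(best["cpaid"]), lead_pos=lead_pos,
            lead_p=float(best["p"]),
            gws_cpaids=members["cpaid"].tolist(),
            gws_positions=[int(x) for x in members["pos"]],
        ))
        # (5) drop all variants inside the borders before the next round
        per_chrom[chrom] = g[(g["pos"] < start) | (g["pos"] > end)].reset_index(drop=True)
    return loci


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def classify_loci(loci: list[Locus],
                  known_regions: list[tuple[str, int, int]]) -> list[Locus]:
    """Set novelty in place: known iff any GWS variant lies in a known region.

    Regions are (chrom, start, end), 1-based closed intervals.  Locus IDs are
    renumbered with "n"/"k" prefixes in discovery order within each class.
    """
    for chrom, start, end in known_regions:
        if start > end:
            raise ValueError(f"malformed known region {chrom}:{start}-{end}")
    n_idx = k_idx = 0
    for locus in loci:
        known = any(
            str(chrom) == locus.chrom and start <= p <= end
            for chrom, start, end in known_regions
            for p in locus.gws_positions
        )
        if known:
            k_idx += 1
            locus.novelty, locus.locus_id = "known", f"k{k_idx}"
        else:
            n_idx += 1
            locus.novelty, locus.locus_id = "novel", f"n{n_idx}"
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view: locus_id, chrom, start, end, lead, p, size, novelty."""
    return pd.DataFrame([
        {"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start, "end": l.end,
         "lead_cpaid": l.lead_cpaid, "lead_p": l.lead_p, "n_gws": l.n_gws,
         "novelty": l.novelty}
        for l in loci
    ])
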