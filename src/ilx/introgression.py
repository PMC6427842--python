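"""Introgression mapping from expression markers and PCR panels.

An introgression line (IL) carries a segment of the N2 genome — the region
around the transgene — inside a wild-isolate background.  Wild-isolate
marker genes, which are expressed differently in the wild background than in
N2, therefore go "missing" (revert to the N2 level) wherever the N2 segment
was introgressed.  The mapper formalises this as nearest-centroid
assignment: for each marker gene, the IL's mean expression is compared to
the N2 centroid and the wild-background centroid; runs of consecutive
N2-like calls along a chromosome become introgression intervals.

A parallel route calls intervals from PCR genotyping panels (indel markers
scored N2 / background / fail), with an explicit uncertainty zone out to the
nearest flanking background calls — precise breakpoints are not resolvable
from sparse marker panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, GeneMap, ValidationError

CALL_BACKGROUND = "background_like"
CALL_N2 = "n2_like"
CALL_AMBIGUOUS = "ambiguous"


@dataclass
class MarkerCall:
    """Call for one marker gene in one line."""

    gene_id: str
    line: str
    call: str
    score: float  # signed: >0 toward N2, <0 toward the wild background


@dataclass
class IntrogressionInterval:
    """A called N2 segment: chromosome span in Mb (1-based inclusive)."""

    line: str
    chromosome: str
    start_mb: float
    end_mb: float
    n_markers: int
    left_ambiguous_mb: float = 0.0
    right_ambiguous_mb: float = 0.0

    def __post_init__(self) -> None:
        if self.end_mb < self.start_mb:
            raise ValidationError("interval end before start")


def call_marker_presence(dataset: ExpressionDataset,
                         marker_genes: list[str],
                         line_genotype: str,
                         background_genotype: str,
                         reference_genotype: str = "N2",
                         margin_fraction: float = 0.5) -> pd.DataFrame:
    """Call each marker in the IL as N2-like, background-like or ambiguous.

    The IL is identified by (genotype == line_genotype, aS == True); its mean
    marker expression is compared to the N2 centroid (all reference-genotype
    samples) and the wild-background centroid (genotype samples without the
    transgene).  The nearest centroid wins; a call is ambiguous when the
    distance difference is below ``margin_fraction`` x the centroid
    separation.  Markers absent from the dataset are skipped with a warning.

    Returns a DataFrame (index gene_id) with columns call, score — the score
    is the signed distance difference, positive toward N2 — and the centroid
    means.
    """
    s = dataset.samples
    il_cols = s.index[(s["genotype"] == line_genotype) & s["aS"]]
    bg_cols = s.index[(s["genotype"] == background_genotype) & ~s["aS"]]
    n2_cols = s.index[s["genotype"] == reference_genotype]
    if len(il_cols) == 0 or len(bg_cols) == 0 or len(n2_cols) == 0:
        raise ValidationError(
            f"need IL ({line_genotype}, aS=1), background ({background_genotype}, "
            f"aS=0) and reference ({reference_genotype}) samples")

    present = [g for g in marker_genes if g in dataset.gene_ids]
    skipped = [g for g in marker_genes if g not in dataset.gene_ids]
    if skipped:
        warnings.warn(f"{len(skipped)} marker gene(s) absent from dataset, skipped",
                      stacklevel=2)
    if not present:
        raise ValidationError("no marker gene present in the dataset")

    sub = dataset.matrix.loc[present]
    il_mean = sub[il_cols].mean(axis=1)
    bg_cent = sub[bg_cols].mean(axis=1)
    n2_cent = sub[n2_cols].mean(axis=1)

    d_n2 = (il_mean - n2_cent).abs()
    d_bg = (il_mean - bg_cent).abs()
    separation = (n2_cent - bg_cent).abs()
    score = d_bg - d_n2  # positive: closer to N2
    margin = margin_fraction * separation
    call = np.where(score.abs() < margin,
                    CALL_AMBIGUOUS,
                    np.where(score > 0, CALL_N2, CALL_BACKGROUND))
    return pd.DataFrame({"call": call, "score": score, "il_mean": il_mean,
                         "n2_centroid": n2_cent, "background_centroid": bg_cent},
                        index=pd.Index(present, name="gene_id"))


def detect_introgression_intervals(calls: pd.DataFrame, gene_map: GeneMap,
                                   line: str, min_run: int = 3,
                                   ) -> list[IntrogressionInterval]:
    """Turn positioned marker calls into introgression intervals.

    Per chromosome (markers in position order), maximal runs containing at
    least ``min_run`` N2-like calls become intervals; ambiguous calls do not
    break a run but do not count toward ``min_run``.  Interval bounds are the
    positions of the outermost N2-like markers.  Lines with no N2-like
    markers yield an empty list.
    """
    pos = gene_map.table.loc[calls.index]
    df = calls.join(pos)
    intervals: list[IntrogressionInterval] = []
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_mb")
        run: list[tuple[float, str]] = []  # (position, call) for current run
        for _, row in sub.iterrows():
            if row["call"] == CALL_BACKGROUND:
                intervals.extend(_close_run(run, line, str(chrom), min_run))
                run = []
            else:
                run.append((float(row["position_mb"]), row["call"]))
        intervals.extend(_close_run(run, line, str(chrom), min_run))
    return intervals


def _close_run(run: list[tuple[float, str]], line: str, chrom: str,
               min_run: int) -> list[IntrogressionInterval]:
    n2_positions = [p for p, c in run if c == CALL_N2]
    if len(n2_positions) < min_run:
        return []
    start, end = n2_positions[0], n2_positions[-1]
    amb_left = [p for p, c in run if c == CALL_AMBIGUOUS and p < start]
    amb_right = [p for p, c in run if c == CALL_AMBIGUOUS and p > end]
    return [IntrogressionInterval(line=line, chromosome=chrom,
                                  start_mb=start, end_mb=end,
                                  n_markers=len(n2_positions),
                                  left_ambiguous_mb=start - min(amb_left) if amb_left else 0.0,
                                  right_ambiguous_mb=max(amb_right) - end if amb_right else 0.0)]


# ---------------------------------------------------------------------------
# PCR-panel route

@dataclass
class PcrInterval:
    """Interval from PCR genotyping with an explicit uncertainty zone."""

    line: str
    chromosome: str
    start_mb: float | None
    end_mb: float | None
    uncertainty_start_mb: float | None
    uncertainty_end_mb: float | None
    n_markers: int

    @property
    def empty(self) -> bool:
        return self.start_mb is None


def interval_from_pcr_markers(panel: pd.DataFrame, line: str,
                              chromosome: str) -> PcrInterval:
    """Interval spanned by N2 calls in a PCR marker panel.

    ``panel`` columns: name, chromosome, position_mb, call (N2 / background /
    fail), line.  The interval runs from the first to the last N2 call on the
    chromosome; the uncertainty zone extends to the nearest flanking
    background calls (or the chromosome's scored extremes when none flank).
    No N2 call on the chromosome yields an empty-interval result; all calls
    failing is an error.
    """
    sub = panel[(panel["line"] == line) & (panel["chromosome"] == chromosome)]
    sub = sub.sort_values("position_mb")
    if len(sub) < 2:
        raise ValidationError(
            f"need >= 2 panel markers on chromosome {chromosome} for {line}")
    scored = sub[sub["call"] != "fail"]
    if scored.empty:
        raise ValidationError(f"all panel markers failed for {line} on {chromosome}")
    n2 = scored[scored["call"] == "N2"]
    if n2.empty:
        return PcrInterval(line=line, chromosome=chromosome, start_mb=None,
                           end_mb=None, uncertainty_start_mb=None,
                           uncertainty_end_mb=None, n_markers=0)
    start = float(n2["position_mb"].iloc[0])
    end = float(n2["position_mb"].iloc[-1])
    bg = scored[scored["call"] == "background"]
    left_bg = bg[bg["position_mb"] < start]["position_mb"]
    right_bg = bg[bg["position_mb"] > end]["position_mb"]
    unc_start = float(left_bg.iloc[-1]) if len(left_bg) else float(
        scored["position_mb"].iloc[0])
    unc_end = float(right_bg.iloc[0]) if len(right_bg) else float(
        scored["position_mb"].iloc[-1])
    return PcrInterval(line=line, chromosome=chromosome, start_mb=start,
                       end_mb=end, uncertainty_start_mb=unc_start,
                       uncertainty_end_mb=unc_end, n_markers=len(n2))


def intervals_to_table(intervals: list[IntrogressionInterval]) -> pd.DataFrame:
    rows = [{"line": iv.line, "chromosome": iv.chromosome,
             "start_mb": iv.start_mb, "end_mb": iv.end_mb,
             "n_markers": iv.n_markers} for iv in intervals]
    out = pd.DataFrame(rows, columns=["line", "chromosome", "start_mb",
                                      "end_mb", "n_markers"])
    out.index.name = "interval"
    return out


def intervals_to_bed(intervals: list[IntrogressionInterval]) -> pd.DataFrame:
    """Intervals as 0-based half-open BED rows (bp)."""
    rows = []
    for iv in intervals:
        rows.append({"chromosome": iv.chromosome,
                     "start": int(round(iv.start_mb * 1e6)) - 1,
                     "end": int(round(iv.end_mb * 1e6)),
                     "name": f"{iv.line}_introgression"})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])
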