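"""Count normalization, filtering, temporal patterns and landscape statistics.

TMM/CPM normalization follows the trimmed-mean-of-M-values recipe: a
reference sample is chosen by upper-quartile proximity to the mean upper
quartile, per-sample scaling factors are weighted trimmed means of per-gene
log2 count ratios (doubly trimmed by M and by average log intensity A), and
factors are rescaled to geometric mean 1. M-values are computed on raw
counts, so the factors absorb both depth and composition differences and a
column that is an exact scalar multiple of the reference recovers that
scalar (up to the geometric-mean rescale).

Variance stabilisation downstream is plain log2(CPM + 1); batch handling is
an optional per-batch median-centering on that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomicInterval, TranscriptModel

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "PatternCall",
    "tmm_normalize",
    "presence_filter",
    "call_patterns",
    "sample_correlation",
    "feature_stats",
    "compare_to_genes",
    "bin_density",
    "neighbor_distance",
    "log_cpm",
    "batch_center",
]


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts plus sample design."""

    values: pd.DataFrame
    sample_design: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative counts")
        if self.sample_design is not None:
            missing = set(self.values.columns) - set(self.sample_design.index)
            if missing:
                raise ValueError(f"samples without design rows: {sorted(missing)}")
            if "stage" not in self.sample_design.columns:
                raise ValueError("sample design must have a 'stage' column")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ExpressionMatrix:
    cpm: pd.DataFrame
    tmm_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")


@dataclass(frozen=True)
class PatternCall:
    feature: str
    label: str  # "stage_specific:<stage>" | "constitutive" | "silent" | "other"


def _counts_frame(counts) -> pd.DataFrame:
    return counts.values if isinstance(counts, CountMatrix) else counts


def tmm_normalize(counts, trim_M: float = 0.30, trim_A: float = 0.05) -> ExpressionMatrix:
    """TMM scaling factors and CPM for a count matrix.

    CPM is count / (library size x factor) x 1e6, so each CPM column sums
    to 1e6 / factor. All-zero samples are rejected by name.
    """
    df = _counts_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = df.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    uq = df.apply(lambda col: np.quantile(col[col > 0], 0.75), axis=0)
    ref = (uq - uq.mean()).abs().idxmin()
    yr = df[ref].to_numpy(dtype=float)
    Nr = float(lib[ref])
    log_factors = {}
    for s in df.columns:
        ys = df[s].to_numpy(dtype=float)
        Ns = float(lib[s])
        mask = (ys > 0) & (yr > 0)
        if s == ref or not mask.any():
            log_factors[s] = 0.0
            continue
        m = np.log2(ys[mask] / yr[mask])
        a = 0.5 * np.log2(ys[mask] * yr[mask])
        lo_m, hi_m = np.quantile(m, [trim_M, 1 - trim_M])
        lo_a, hi_a = np.quantile(a, [trim_A, 1 - trim_A])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep[:] = True
        w = 1.0 / ((Ns - ys[mask]) / (Ns * ys[mask])
                   + (Nr - yr[mask]) / (Nr * yr[mask]))
        log_factors[s] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    logf = pd.Series(log_factors)[df.columns]
    logf = logf - logf.mean()  # geometric mean of factors -> 1
    factors = 2.0 ** logf
    cpm = df / (lib * factors) * 1e6
    return ExpressionMatrix(cpm=cpm, tmm_factors=factors)


def presence_filter(counts, min_reads: int = 10, min_fraction: float = 0.6):
    """Keep features with more than ``min_reads`` reads in more than
    ``min_fraction`` of samples.

    ``threshold_k = floor(min_fraction * n_samples)``; a feature is kept iff
    the number of samples with count strictly above ``min_reads`` is
    strictly above ``threshold_k``. With 72 samples at fraction 0.6 this is
    the "more than 43 of 72" rule. Returns ``(kept ids, threshold_k)``.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    df = _counts_frame(counts)
    threshold_k = math.floor(min_fraction * df.shape[1])
    n_expressed = (df > min_reads).sum(axis=1)
    kept = list(df.index[n_expressed > threshold_k])
    return kept, threshold_k


def call_patterns(expr: ExpressionMatrix | pd.DataFrame, design: pd.DataFrame,
                  expressed_cpm: float = 1.0) -> list[PatternCall]:
    """Temporal pattern per feature from stage-mean CPM.

    stage_specific:<s> if mean CPM >= ``expressed_cpm`` in exactly stage s,
    constitutive if in all stages, silent if in none, other otherwise.
    """
    cpm = expr.cpm if isinstance(expr, ExpressionMatrix) else expr
    stages = design.loc[cpm.columns, "stage"]
    if stages.nunique() < 2:
        raise ValueError("need at least 2 stages")
    stage_means = cpm.T.groupby(stages).mean().T  # features x stages
    expressed = stage_means >= expressed_cpm
    calls = []
    for feat, row in expressed.iterrows():
        n_on = int(row.sum())
        if n_on == 0:
            label = "silent"
        elif n_on == len(row):
            label = "constitutive"
        elif n_on == 1:
            label = f"stage_specific:{row.index[row][0]}"
        else:
            label = "other"
        calls.append(PatternCall(feat, label))
    return calls


def log_cpm(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    cpm = expr.cpm if isinstance(expr, ExpressionMatrix) else expr
    return np.log2(cpm + 1.0)


def batch_center(logexpr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Median-center each batch per feature on the log scale (optional)."""
    out = logexpr.copy()
    grand = logexpr.median(axis=1)
    for batch in batches.unique():
        cols = batches.index[batches == batch]
        cols = [c for c in cols if c in out.columns]
        med = out[cols].median(axis=1)
        out[cols] = out[cols].sub(med - grand, axis=0)
    return out


def sample_correlation(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between samples on log2(CPM+1).

    Zero-variance samples get NaN off-diagonal entries (undefined marker)
    rather than raising; the diagonal is exactly 1.
    """
    le = log_cpm(expr)
    if le.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = le.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[np.isnan(corr)] = np.nan
    bad = np.where(sd == 0)[0]
    for i in bad:
        corr[i, :] = np.nan
        corr[:, i] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=le.columns, columns=le.columns)


def feature_stats(transcripts, sequences: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-feature spliced length, exon count and GC percentage.

    Accepts transcripts or discovery calls; GC ignores N bases.
    """
    rows = {}
    for item in transcripts:
        t: TranscriptModel = getattr(item, "transcript", item)
        seq = t.sequence
        if seq is None and sequences is not None:
            seq = sequences.get(t.id)
        if seq is None:
            raise ValueError(f"no sequence for {t.id}")
        seq = seq.upper()
        informative = len(seq) - seq.count("N")
        gc = 100.0 * (seq.count("G") + seq.count("C")) / informative if informative else float("nan")
        rows[t.id] = {"length": t.spliced_length, "n_exons": t.n_exons,
                      "gc_percent": gc}
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_to_genes(lnc_stats: pd.DataFrame, gene_stats: pd.DataFrame) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p-value per landscape metric.

    No multiplicity correction is applied; the three metrics are reported
    side by side as independent comparisons.
    """
    if len(lnc_stats) < 2 or len(gene_stats) < 2:
        raise ValueError("both groups need at least 2 members")
    out = {}
    for metric in ("length", "n_exons", "gc_percent"):
        res = stats.mannwhitneyu(lnc_stats[metric], gene_stats[metric],
                                 alternative="two-sided")
        out[metric] = float(res.pvalue)
    return out


def bin_density(features, chrom_sizes: dict[str, int],
                bin_size: int = 100_000) -> dict[str, np.ndarray]:
    """Per-chromosome counts of feature starts in fixed genomic bins."""
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    bins = {c: np.zeros(max(1, -(-size // bin_size)), dtype=int)
            for c, size in chrom_sizes.items()}
    for item in features:
        t: TranscriptModel = getattr(item, "transcript", item)
        size = chrom_sizes.get(t.chrom)
        if size is None or t.start >= size:
            raise ValueError(f"feature {t.id} beyond chromosome bounds")
        bins[t.chrom][t.start // bin_size] += 1
    return bins


def neighbor_distance(lincs, genes) -> dict[str, float | None]:
    """Signed distance from each lincRNA to its nearest gene.

    Negative: the lincRNA lies on the gene's 5' side, measured from the
    lincRNA TSS to the gene 5' boundary. Positive: the lincRNA lies 3' of
    the gene, measured from the gene 3' end. Overlapping spans give 0;
    chromosomes without genes give None.
    """
    gene_list = [getattr(g, "transcript", g) for g in genes]
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, float | None] = {}
    for item in lincs:
        t: TranscriptModel = getattr(item, "transcript", item)
        candidates = by_chrom.get(t.chrom)
        if not candidates:
            out[t.id] = None
            continue

        def gap(g: TranscriptModel) -> int:
            if t.start < g.end and g.start < t.end:
                return 0
            return g.start - t.end if t.end <= g.start else t.start - g.end

        nearest = min(candidates, key=lambda g: (gap(g), g.start, g.id))
        if gap(nearest) == 0:
            out[t.id] = 0.0
            continue
        # orientation relative to the gene's own strand
        linc_left_of_gene = t.end <= nearest.start
        gene_plus = nearest.strand == "+"
        on_5prime_side = linc_left_of_gene == gene_plus
        if on_5prime_side:
            gene_5p = nearest.start if gene_plus else nearest.end - 1
            out[t.id] = float(-abs(gene_5p - t.tss))
        else:
            gap_3p = (t.start - nearest.end) if gene_plus else (nearest.start - t.end)
            out[t.id] = float(gap_3p)
    return out
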