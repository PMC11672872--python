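"""Query-vs-reference length-distribution and exon-count comparisons.

Transcript-region lengths (full mRNA, 5'UTR, CDS, 3'UTR) are compared between
a query list of transcripts and a reference exome with a two-sample t-test on
log10 lengths, plus Gaussian-KDE density curves for plotting.  Exon-count
spectra compare per-gene mean exon counts (binned 1..9 and "10+") with a
chi-squared goodness-of-fit test against reference proportions.

Lengths are tested on the log10 scale by default because mRNA region lengths
are strongly right-skewed and approximately log-normal; Welch's unequal-
variance form is the default because query lists are small relative to the
reference exome and need not share its variance.  Both choices can be
overridden (``scale='linear'``, ``test='student'``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .transcript_models import TranscriptModel, region_lengths

log = logging.getLogger(__name__)

REGIONS = ("full", "utr5", "cds", "utr3")

_REGION_ATTR = {"full": "len_full", "utr5": "len_5utr", "cds": "len_cds", "utr3": "len_3utr"}


class StatisticsError(ValueError):
    """Raised when a comparison cannot be computed (e.g. too few lengths)."""


@dataclass
class LengthSample:
    """Lengths (nt) of one region for one labelled transcript set."""

    region: str
    values: List[float]
    label: str = "query"

    def positive(self) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        return arr[arr > 0]

    @property
    def n_zero(self) -> int:
        arr = np.asarray(self.values, dtype=float)
        return int((arr <= 0).sum())


@dataclass
class DistributionComparison:
    region: str
    n_query: int
    n_reference: int
    t_statistic: float
    p_value: float
    direction: str  # longer | shorter | none
    n_zero_query: int = 0
    n_zero_reference: int = 0
    density_query: Optional[Tuple[np.ndarray, np.ndarray]] = None
    density_reference: Optional[Tuple[np.ndarray, np.ndarray]] = None


@dataclass
class ExonCountSpectrum:
    bins: List[str]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p_value: float
    merged_bins: List[str] = field(default_factory=list)


def length_sample(models: Iterable[TranscriptModel], region: str, label: str = "query") -> LengthSample:
    """Collect one region's lengths over the *coding* transcripts of a set."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    vals = []
    for t in models:
        rl = region_lengths(t)
        if not rl.coding:
            continue
        vals.append(float(getattr(rl, _REGION_ATTR[region])))
    return LengthSample(region=region, values=vals, label=label)


def compare_lengths(
    query: LengthSample,
    reference: LengthSample,
    alpha: float = 0.05,
    test: str = "welch",
    scale: str = "log10",
    compute_density: bool = True,
    grid_size: int = 256,
) -> DistributionComparison:
    """Two-sample test of query vs reference lengths, with density curves.

    Zero-length regions (a transcript with no annotated UTR) are excluded from
    the log-scale test and reported separately in the zero counts.
    """
    if test not in ("welch", "student"):
        raise ValueError(f"test must be 'welch' or 'student', got {test!r}")
    if scale not in ("log10", "linear"):
        raise ValueError(f"scale must be 'log10' or 'linear', got {scale!r}")

    q = query.positive()
    r = reference.positive()
    if len(q) < 3 or len(r) < 3:
        raise StatisticsError(
            f"region {query.region}: need >= 3 positive lengths per sample "
            f"(query {len(q)}, reference {len(r)})"
        )
    xq = np.log10(q) if scale == "log10" else q
    xr = np.log10(r) if scale == "log10" else r

    if np.array_equal(np.sort(xq), np.sort(xr)):
        # identical samples: the test statistic is exactly zero
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(xq, xr, equal_var=(test == "student"))
        t_stat, p = float(t_stat), float(p)

    if p <= alpha:
        direction = "longer" if xq.mean() > xr.mean() else "shorter"
    else:
        direction = "none"

    dq = dr = None
    if compute_density:
        grid = _shared_grid(xq, xr, grid_size)
        dq = (grid, _kde(xq, grid))
        dr = (grid, _kde(xr, grid))

    return DistributionComparison(
        region=query.region,
        n_query=len(q),
        n_reference=len(r),
        t_statistic=t_stat,
        p_value=p,
        direction=direction,
        n_zero_query=query.n_zero,
        n_zero_reference=reference.n_zero,
        density_query=dq,
        density_reference=dr,
    )


def _shared_grid(xq: np.ndarray, xr: np.ndarray, n: int) -> np.ndarray:
    lo = min(xq.min(), xr.min())
    hi = max(xq.max(), xr.max())
    pad = 0.1 * (hi - lo + 1e-9)
    return np.linspace(lo - pad, hi + pad, n)


def _kde(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if np.ptp(x) == 0:
        # degenerate sample: a narrow Gaussian bump centred on the value
        sd = max(abs(x[0]) * 1e-3, 1e-3)
        return sps.norm.pdf(grid, loc=x[0], scale=sd)
    kde = sps.gaussian_kde(x, bw_method="silverman")
    return kde(grid)


# ---------------------------------------------------------------------------
# Exon-count spectra


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mean_exon_counts(genes: Mapping[str, Sequence[TranscriptModel]]) -> Dict[str, float]:
    """Per-gene mean exon count across that gene's isoforms."""
    out = {}
    for gene, models in genes.items():
        if not models:
            raise ValueError(f"gene {gene}: no transcripts")
        out[gene] = float(np.mean([t.n_exons for t in models]))
    return out


def _bin_counts(means: Iterable[float], n_bins: int = 10) -> np.ndarray:
    counts = np.zeros(n_bins, dtype=float)
    for m in means:
        k = max(1, _round_half_up(m))
        counts[min(k, n_bins) - 1] += 1
    return counts


def exon_count_spectrum(
    query_genes: Mapping[str, Sequence[TranscriptModel]],
    reference_genes: Mapping[str, Sequence[TranscriptModel]],
) -> ExonCountSpectrum:
    """Chi-squared goodness-of-fit of query exon-count bins vs reference.

    Per-gene exon count is the mean across the gene's isoforms, rounded half-up
    for binning into categories 1..9 and "10+".  Expected counts are reference
    bin proportions scaled to the query total; zero-expected bins are merged
    into the next bin up (logged).
    """
    bins = [str(i) for i in range(1, 10)] + ["10+"]
    obs = _bin_counts(mean_exon_counts(query_genes).values())
    ref = _bin_counts(mean_exon_counts(reference_genes).values())
    if ref.sum() == 0 or obs.sum() == 0:
        raise StatisticsError("exon-count spectrum needs non-empty query and reference")

    merged: List[str] = []
    labels = list(bins)
    i = 0
    while i < len(ref):
        if ref[i] == 0:
            j = i + 1 if i + 1 < len(ref) else i - 1  # merge upward, last bin folds down
            ref[j] += ref[i]
            obs[j] += obs[i]
            merged.append(labels[i])
            ref = np.delete(ref, i)
            obs = np.delete(obs, i)
            del labels[i]
        else:
            i += 1
    if merged:
        log.info("exon spectrum: merged zero-expected bins %s", merged)

    expected = ref / ref.sum() * obs.sum()
    chi2, p = sps.chisquare(obs, expected)
    return ExonCountSpectrum(
        bins=labels,
        observed=obs,
        expected=expected,
        chi2=float(chi2),
        p_value=float(p),
        merged_bins=merged,
    )


# ---------------------------------------------------------------------------
# Reporting


def lengthome_report(
    comparisons: Sequence[Tuple[str, DistributionComparison]],
    spectra: Sequence[Tuple[str, ExonCountSpectrum]],
    out: Union[str, Path],
    header_lines: Sequence[str] = (),
    plots: bool = True,
) -> Dict[str, Path]:
    """Write a statistics TSV plus one density-overlay plot per comparison.

    ``comparisons``/``spectra`` are (condition label, result) pairs.  Returns a
    mapping of artefact names to written paths.
    """
    if not comparisons:
        raise ValueError("lengthome_report needs at least one comparison")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    stats_path = out / "length_stats.tsv"
    with open(stats_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("region\tcondition\tn_query\tn_ref\tn_zero_query\tt\tp\tdirection\n")
        for cond, c in comparisons:
            fh.write(
                f"{c.region}\t{cond}\t{c.n_query}\t{c.n_reference}\t{c.n_zero_query}\t"
                f"{c.t_statistic:.6g}\t{c.p_value:.6g}\t{c.direction}\n"
            )
    written["length_stats"] = stats_path

    if spectra:
        spec_path = out / "exon_spectra.tsv"
        with open(spec_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("condition\tbin\tobserved\texpected\tchi2\tp\n")
            for cond, s in spectra:
                for b, o, e in zip(s.bins, s.observed, s.expected):
                    fh.write(f"{cond}\t{b}\t{o:.6g}\t{e:.6g}\t{s.chi2:.6g}\t{s.p_value:.6g}\n")
        written["exon_spectra"] = spec_path

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for cond, c in comparisons:
            if c.density_query is None:
                continue
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(*c.density_reference, color="crimson", label="reference exome")
            ax.plot(*c.density_query, color="steelblue", label=f"query ({cond})")
            ax.set_xlabel("log10 length (bp)")
            ax.set_ylabel("density")
            ax.set_title(f"{c.region} — {cond} (p={c.p_value:.3g}, {c.direction})")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            p = out / f"density_{c.region}_{cond}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written[f"plot_{c.region}_{cond}"] = p
    return written
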