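"""Spatiotemporal abundance statistics for curated contigs.

The central quantity is the interquartile-mean coverage: the mean of the
second and third quartiles of a contig's sorted per-base read depths.
Conserved genes (e.g. shared structural modules) attract reads from
related phages and inflate coverage locally; discarding the top and
bottom quartile of positions makes the per-sample abundance estimate
robust to such spikes.

Relative abundance is the proportion of nucleotides mapped to a contig
out of nucleotides mapped to all curated contigs in that sample.
Temporal variability is summarized by the mean-normalized variance
(index of dispersion): the population variance of a contig's relative
abundance through time divided by its temporal mean, which removes the
preferential weighting of high-abundance contigs.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import BIN_ORDER, SURFACE_DEPTHS, depth_bin, validate_samples
from .exceptions import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interquartile-mean coverage
# ---------------------------------------------------------------------------


def _iqr_window(n_positions: int) -> tuple[int, int]:
    """Half-open 0-based rank window [ceil(L/4), floor(3L/4)) of the middle half."""
    if n_positions < 4:
        raise DataError(f"interquartile mean needs >= 4 positions, got {n_positions}")
    lo = math.ceil(n_positions / 4)
    hi = math.floor(3 * n_positions / 4)
    return lo, hi


def iqr_mean(depth_vector: Iterable[float]) -> float:
    """Interquartile-mean of a per-base depth vector.

    Sort the L per-base depths ascending and average the positions whose
    0-based rank falls in [ceil(L/4), floor(3L/4)). Deterministic rank
    slicing, no quantile interpolation.
    """
    x = np.asarray(list(depth_vector) if not isinstance(depth_vector, np.ndarray) else depth_vector, dtype=float)
    if x.ndim != 1:
        raise DataError("depth vector must be one-dimensional")
    lo, hi = _iqr_window(x.size)
    return float(np.sort(x, kind="stable")[lo:hi].mean())


def iqr_mean_rle(depths: np.ndarray, lengths: np.ndarray) -> float:
    """Interquartile-mean of a run-length encoded per-base depth vector.

    Equivalent to expanding the runs and calling :func:`iqr_mean`, but
    computed on weighted ranks so long contigs never materialize.
    """
    d = np.asarray(depths, dtype=float)
    w = np.asarray(lengths, dtype=np.int64)
    if d.shape != w.shape or d.ndim != 1:
        raise DataError("depths and lengths must be matching 1-d arrays")
    if (w <= 0).any():
        raise DataError("run lengths must be positive")
    total = int(w.sum())
    lo, hi = _iqr_window(total)
    order = np.argsort(d, kind="stable")
    d, w = d[order], w[order]
    cum = np.cumsum(w)
    start = cum - w
    take = np.clip(np.minimum(cum, hi) - np.maximum(start, lo), 0, None)
    return float((d * take).sum() / (hi - lo))


# ---------------------------------------------------------------------------
# Coverage container
# ---------------------------------------------------------------------------


class CoverageTable:
    """Per-contig x per-sample run-length encoded read depth.

    Internally a mapping ``(contig_id, sample_id) -> (depths, run_lengths)``.
    Cells absent from the mapping are zero coverage. Derived matrices
    (interquartile-mean coverage, nucleotides mapped) are cached.
    """

    def __init__(
        self,
        runs: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
        contig_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> None:
        self._runs = {
            key: (np.asarray(dep, dtype=np.int64), np.asarray(ln, dtype=np.int64))
            for key, (dep, ln) in runs.items()
        }
        for (cid, sid), (dep, ln) in self._runs.items():
            if dep.shape != ln.shape:
                raise DataError(f"ragged runs for ({cid}, {sid})")
            if (dep < 0).any() or (ln <= 0).any():
                raise DataError(f"negative depth or nonpositive run length for ({cid}, {sid})")
        if contig_ids is None:
            contig_ids = sorted({cid for cid, _ in self._runs})
        if sample_ids is None:
            sample_ids = sorted({sid for _, sid in self._runs})
        self.contig_ids = list(contig_ids)
        self.sample_ids = list(sample_ids)
        self._nt: pd.DataFrame | None = None
        self._iqr: pd.DataFrame | None = None

    def runs(self, contig_id: str, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        return self._runs[(contig_id, sample_id)]

    def nucleotides_mapped(self) -> pd.DataFrame:
        """Total mapped nucleotides (sum of depth x run length) per contig x sample."""
        if self._nt is None:
            mat = pd.DataFrame(0.0, index=self.contig_ids, columns=self.sample_ids)
            for (cid, sid), (dep, ln) in self._runs.items():
                mat.loc[cid, sid] = float((dep * ln).sum())
            self._nt = mat
        return self._nt

    def iqr_mean_matrix(self) -> pd.DataFrame:
        """Interquartile-mean coverage per contig x sample (0 for absent cells)."""
        if self._iqr is None:
            mat = pd.DataFrame(0.0, index=self.contig_ids, columns=self.sample_ids)
            for (cid, sid), (dep, ln) in self._runs.items():
                mat.loc[cid, sid] = iqr_mean_rle(dep, ln)
            self._iqr = mat
        return self._iqr

    def subset(self, contig_ids: Iterable[str]) -> "CoverageTable":
        keep = set(contig_ids)
        runs = {k: v for k, v in self._runs.items() if k[0] in keep}
        return CoverageTable(runs, [c for c in self.contig_ids if c in keep], self.sample_ids)

    # -- serialization ------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format run-length table: contig_id, sample_id, run_start, run_length, depth."""
        frames = []
        for cid in self.contig_ids:
            for sid in self.sample_ids:
                if (cid, sid) not in self._runs:
                    continue
                dep, ln = self._runs[(cid, sid)]
                start = np.concatenate([[0], np.cumsum(ln)[:-1]])
                frames.append(
                    pd.DataFrame(
                        {
                            "contig_id": cid,
                            "sample_id": sid,
                            "run_start": start,
                            "run_length": ln,
                            "depth": dep,
                        }
                    )
                )
        if not frames:
            return pd.DataFrame(columns=["contig_id", "sample_id", "run_start", "run_length", "depth"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CoverageTable":
        required = {"contig_id", "sample_id", "run_start", "run_length", "depth"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"coverage table missing columns: {sorted(missing)}")
        runs = {}
        for (cid, sid), grp in df.groupby(["contig_id", "sample_id"], sort=True):
            grp = grp.sort_values("run_start", kind="stable")
            runs[(str(cid), str(sid))] = (
                grp["depth"].to_numpy(np.int64),
                grp["run_length"].to_numpy(np.int64),
            )
        return cls(runs)


# ---------------------------------------------------------------------------
# Relative abundance and dispersion
# ---------------------------------------------------------------------------


def relative_abundance(
    coverage: CoverageTable,
    contig_ids: Iterable[str] | None = None,
    on_zero_sample: str = "raise",
) -> pd.DataFrame:
    """Per-sample proportion of nucleotides mapped to each contig.

    The denominator is nucleotides mapped to the supplied (curated)
    contigs only, so columns sum to 1. Samples with zero total mapping
    either raise (``on_zero_sample='raise'``) or are dropped with a
    warning (``'drop'``).
    """
    nt = coverage.nucleotides_mapped()
    if contig_ids is not None:
        nt = nt.loc[[c for c in coverage.contig_ids if c in set(contig_ids)]]
    totals = nt.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        if on_zero_sample == "drop":
            warnings.warn(f"dropping {len(zero)} sample(s) with zero total mapping: {zero[:5]}")
            nt = nt.drop(columns=zero)
            totals = totals.drop(index=zero)
        else:
            raise DataError(f"sample(s) with zero total mapping: {zero[:5]}")
    return nt.div(totals, axis=1)


def mean_normalized_variance(series: Iterable[float]) -> float:
    """Population variance of a temporal series divided by its mean.

    The index of dispersion of the relative-abundance series of one
    contig within one depth bin. Undefined (NaN, with a warning) when the
    mean is zero; requires at least two timepoints. Scaling the series by
    c > 0 scales the statistic by c, which is exactly what equalizes the
    weight of high- and low-abundance contigs relative to raw variance.
    """
    x = np.asarray(list(series) if not isinstance(series, np.ndarray) else series, dtype=float)
    if x.size < 2:
        raise DataError(f"dispersion needs >= 2 timepoints, got {x.size}")
    m = x.mean()
    if m == 0:
        warnings.warn("mean abundance is zero; dispersion undefined (NaN)")
        return float("nan")
    return float(x.var() / m)  # population variance (divisor T)


def _per_date_series(rel_ab: pd.DataFrame, samples: pd.DataFrame, depths: Iterable[int]) -> pd.DataFrame:
    """Contig x date matrix: mean relative abundance across the given depths per date."""
    meta = samples.set_index("sample_id")
    cols = [s for s in rel_ab.columns if meta.loc[s, "depth_m"] in set(depths)]
    if not cols:
        raise DataError(f"no samples at depths {sorted(set(depths))}")
    dates = meta.loc[cols, "date"]
    return rel_ab[cols].T.groupby(dates.values).mean().T


def dispersion_by_depth(
    rel_ab: pd.DataFrame,
    samples: pd.DataFrame,
    level: str = "depth",
    presence_floor: float = 0.0,
) -> pd.DataFrame:
    """Mean-normalized variance of each contig within each depth (or bin).

    ``level='depth'`` computes one dispersion per sampling depth;
    ``level='bin'`` first averages relative abundance across a habitat
    bin's depths per date. Contigs whose mean abundance in a column does
    not exceed ``presence_floor`` get NaN (treated as absent there).
    """
    samples = validate_samples(samples)
    if level == "depth":
        columns = sorted(samples["depth_m"].unique())
        groups = {d: [d] for d in columns}
    elif level == "bin":
        columns = [b for b in BIN_ORDER if any(depth_bin(d) == b for d in samples["depth_m"].unique())]
        groups = {b: [d for d in samples["depth_m"].unique() if depth_bin(d) == b] for b in columns}
    else:
        raise DataError(f"unknown level {level!r}")
    out = pd.DataFrame(index=rel_ab.index, columns=columns, dtype=float)
    for col, depths in groups.items():
        series = _per_date_series(rel_ab, samples, depths)
        means = series.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disp = series.var(axis=1, ddof=0) / means
        disp[means <= presence_floor] = np.nan
        out[col] = disp
    return out


def top_k_per_depth(
    rel_ab: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = 13,
) -> dict[int, list[str]]:
    """The k most abundant contigs per sampling depth.

    Contigs are ranked by mean relative abundance across the depth's
    timepoints; ties break lexicographically by contig id. If fewer than
    k contigs are available, all are returned with a warning.
    """
    samples = validate_samples(samples)
    out: dict[int, list[str]] = {}
    for d in sorted(samples["depth_m"].unique()):
        series = _per_date_series(rel_ab, samples, [d]).mean(axis=1)
        ranked = series.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
        if k > len(ranked):
            warnings.warn(f"requested top {k} but only {len(ranked)} contigs available at {d} m")
        out[int(d)] = ranked.index[:k].tolist()
    return out


# ---------------------------------------------------------------------------
# Depth-group assignment
# ---------------------------------------------------------------------------


def assign_depth_groups(
    coverage: CoverageTable,
    samples: pd.DataFrame,
    contig_ids: Iterable[str] | None = None,
    sporadic_threshold: float | None = None,
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assign every contig to one of five distribution groups.

    A contig's persistent bin is the habitat bin where its mean
    interquartile-mean coverage peaks (ties resolve shallow-first). If
    the contig's dispersion within that bin exceeds ``sporadic_threshold``
    it is labelled sporadic instead. The default threshold is the 90th
    percentile of all contigs' dispersion values (data-adaptive surrogate
    for manual binning); an overrides mapping gives exact manual control.

    Returns a frame indexed by contig with columns ``group``,
    ``peak_bin``, ``dispersion``.
    """
    samples = validate_samples(samples)
    if contig_ids is not None:
        coverage = coverage.subset(contig_ids)
    iqr = coverage.iqr_mean_matrix()
    if iqr.to_numpy().sum(axis=None) == 0:
        raise DataError("no contig has any coverage anywhere")
    meta = samples.set_index("sample_id")
    bins_present = [b for b in BIN_ORDER if any(depth_bin(d) == b for d in samples["depth_m"].unique())]
    bin_means = pd.DataFrame(index=iqr.index, columns=bins_present, dtype=float)
    for b in bins_present:
        cols = [s for s in iqr.columns if depth_bin(meta.loc[s, "depth_m"]) == b]
        bin_means[b] = iqr[cols].mean(axis=1)
    absent = bin_means.sum(axis=1) == 0
    if absent.any():
        raise DataError(f"contig(s) absent everywhere: {bin_means.index[absent].tolist()[:5]}")
    # shallow-first tie break: idxmax over columns in BIN_ORDER order
    peak = bin_means.idxmax(axis=1)

    rel = relative_abundance(coverage, on_zero_sample="drop")
    disp_bin = dispersion_by_depth(rel, samples[samples["sample_id"].isin(rel.columns)], level="bin")
    dispersion = pd.Series(
        [disp_bin.loc[c, peak[c]] for c in bin_means.index], index=bin_means.index, dtype=float
    )
    if sporadic_threshold is None:
        sporadic_threshold = float(np.nanpercentile(dispersion.to_numpy(), 90))
        logger.info("sporadic threshold (90th percentile of dispersion): %.4g", sporadic_threshold)
    group = peak.where(~(dispersion > sporadic_threshold), other="sporadic")
    if overrides:
        for cid, g in overrides.items():
            if cid in group.index:
                group[cid] = g
    return pd.DataFrame({"group": group, "peak_bin": peak, "dispersion": dispersion})


def surface_depths() -> tuple[int, ...]:
    return SURFACE_DEPTHS
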