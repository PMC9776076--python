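"""Histogram mutual-information connectivity with Freedman-Diaconis binning.

Functional connectivity between two channels is estimated as the plug-in
(maximum-likelihood) mutual information of their 2-D histogram. The number
of bins per axis follows the Freedman-Diaconis rule applied to each channel
separately, per epoch:

    h = 2 * IQR(x) * n**(-1/3),      bins = ceil((max - min) / h)

with a single bin when the data are degenerate (zero IQR or zero range).
MI is reported in nats,

    MI = sum_ij p_ij * ln( p_ij / (p_i p_j) ),

with empty joint cells contributing zero. No bias correction is applied.

Per-epoch channel-pair MI matrices are averaged over epochs into a stage
matrix, which is then max-normalized ("weight conversion") so that the
largest off-diagonal weight is 1 and the diagonal is 0.

The per-epoch all-pairs computation is vectorized through a single
``bincount`` over offset-encoded joint bin codes using the identity

    MI = (1/n) sum_cells c*ln(c) - m_x - m_y + ln(n),
    m_x = (1/n) sum_samples ln( c_x[bin_x(s)] ),

which avoids materializing per-pair joint tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import xlogy


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class ConnectivityMatrix:
    """A symmetric nonnegative weighted matrix over channels.

    ``normalized`` marks max-normalized weights (max off-diagonal = 1 unless
    the matrix is all zero). MI values are in nats.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    band: str | None = None
    stage: int | None = None
    normalized: bool = False
    mi_units: str = "nats"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {values.shape}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DifferenceMatrix:
    """Entrywise difference of two normalized connectivity matrices."""

    labels: tuple[str, ...]
    values: np.ndarray
    contrast: tuple[int | None, int | None]
    band: str | None = None


# ---------------------------------------------------------------------------
# binning

def fd_bin_count(x: np.ndarray) -> int:
    """Number of histogram bins for ``x`` under the Freedman-Diaconis rule.

    Returns 1 for degenerate input (zero interquartile range or zero range).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = q75 - q25
    lo, hi = x.min(), x.max()
    if iqr <= 0 or hi <= lo:
        return 1
    h = 2.0 * iqr * n ** (-1.0 / 3.0)
    return int(np.ceil((hi - lo) / h))


def _digitize_fd(x: np.ndarray) -> tuple[np.ndarray, int]:
    """FD bin index of every sample on a uniform grid over [min, max]."""
    nb = fd_bin_count(x)
    if nb == 1:
        return np.zeros(x.size, dtype=np.int64), 1
    lo, hi = x.min(), x.max()
    idx = np.floor((x - lo) * (nb / (hi - lo))).astype(np.int64)
    np.clip(idx, 0, nb - 1, out=idx)
    return idx, nb


# ---------------------------------------------------------------------------
# mutual information

def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in histogram MI between two sample vectors, in nats.

    The joint histogram uses ``fd_bin_count(x) x fd_bin_count(y)`` uniform
    bins. Nonnegative up to floating-point rounding (clipped at 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    bx, nx = _digitize_fd(x)
    by, ny = _digitize_fd(y)
    joint = np.bincount(bx * ny + by, minlength=nx * ny).astype(float)
    cx = np.bincount(bx, minlength=nx).astype(float)
    cy = np.bincount(by, minlength=ny).astype(float)
    mi = (xlogy(joint, joint).sum()
          - np.log(cx[bx]).sum() - np.log(cy[by]).sum()) / n + np.log(n)
    return float(max(mi, 0.0))


def epoch_mi_matrix(epoch: np.ndarray,
                    labels: tuple[str, ...] | None = None,
                    band: str | None = None,
                    stage: int | None = None) -> ConnectivityMatrix:
    """All-pairs MI matrix for one epoch (channels x samples block)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("epoch must be (>=2 channels) x samples")
    values = _epoch_mi_values(epoch)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(epoch.shape[0]))
    return ConnectivityMatrix(labels=tuple(labels), values=values, band=band,
                              stage=stage, normalized=False)


def _epoch_mi_values(epoch: np.ndarray) -> np.ndarray:
    """Vectorized all-pairs plug-in MI for one channels x samples block."""
    c, n = epoch.shape
    # FD binning for every channel at once (same arithmetic as fd_bin_count)
    q75, q25 = np.percentile(epoch, [75.0, 25.0], axis=1)
    lo, hi = epoch.min(axis=1), epoch.max(axis=1)
    h = 2.0 * (q75 - q25) * n ** (-1.0 / 3.0)
    ok = (h > 0) & (hi > lo)
    nbins = np.ones(c, dtype=np.int64)
    nbins[ok] = np.ceil((hi[ok] - lo[ok]) / h[ok]).astype(np.int64)
    scale = np.where(ok, nbins / np.where(hi > lo, hi - lo, 1.0), 0.0)
    codes = np.floor((epoch - lo[:, None]) * scale[:, None]).astype(np.int64)
    np.clip(codes, 0, (nbins - 1)[:, None], out=codes)
    marg = np.empty(c)             # m_c = (1/n) sum_s ln c_c[b_c(s)]
    for i in range(c):
        cnt = np.bincount(codes[i], minlength=nbins[i]).astype(float)
        marg[i] = np.log(cnt[codes[i]]).mean()

    iu, ju = np.triu_indices(c, k=1)
    sizes = nbins[iu] * nbins[ju]
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    # offset-encoded joint bin codes for every pair, one flat bincount
    flat = (codes[iu] * nbins[ju][:, None] + codes[ju]
            + starts[:, None]).ravel()
    joint = np.bincount(flat, minlength=int(sizes.sum())).astype(float)
    joint_term = np.add.reduceat(xlogy(joint, joint), starts)
    mi = joint_term / n - marg[iu] - marg[ju] + np.log(n)
    np.clip(mi, 0.0, None, out=mi)

    values = np.zeros((c, c))
    values[iu, ju] = mi
    values[ju, iu] = mi
    return values


def stage_mi_matrix(es) -> ConnectivityMatrix:
    """Entrywise mean of per-epoch MI matrices over all epochs of a stage."""
    if es.n_epochs < 1:
        raise ValueError("empty epoch set")
    acc = np.zeros((len(es.labels),) * 2)
    for ep in es.epochs:
        acc += _epoch_mi_values(ep)
    acc /= es.n_epochs
    band = es.band.name if es.band is not None else None
    return ConnectivityMatrix(labels=tuple(es.labels), values=acc, band=band,
                              stage=es.stage, normalized=False)


# ---------------------------------------------------------------------------
# weight conversion and contrasts

def normalize_weights(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Max-normalize a connectivity matrix ("weight conversion").

    Zeroes the diagonal and divides by the largest absolute off-diagonal
    entry so weights lie in [0, 1]; an all-zero matrix is returned unchanged.
    Idempotent.
    """
    values = np.array(m.values, dtype=float)
    np.fill_diagonal(values, 0.0)
    peak = np.abs(values).max()
    if peak > 0:
        values = values / peak
    return replace(m, values=values, normalized=True)


def matrix_difference(a: ConnectivityMatrix,
                      b: ConnectivityMatrix) -> DifferenceMatrix:
    """Entrywise contrast ``a - b`` of two normalized stage matrices."""
    if a.labels != b.labels:
        raise ValueError("label mismatch between matrices")
    if a.band != b.band:
        raise ValueError(f"band mismatch: {a.band} vs {b.band}")
    if not (a.normalized and b.normalized):
        raise ValueError("difference is defined on normalized matrices")
    return DifferenceMatrix(labels=a.labels, values=a.values - b.values,
                            contrast=(a.stage, b.stage), band=a.band)


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.3 * 29 = 8.7 -> 9, 10.5 -> 11)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def top_fraction_edges(m: ConnectivityMatrix, q: float = 0.3,
                       ) -> list[tuple[str, str, float]]:
    """The strongest fraction ``q`` of edges as (label_i, label_j, weight).

    Takes the ``round(q * n_edges)`` largest upper-triangle entries
    (round half away from zero), sorted by descending weight with ties
    broken lexicographically on the label pair.
    """
    if not 0 < q <= 1:
        raise ValueError("edge fraction must be in (0, 1]")
    n = m.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    iu, ju = np.triu_indices(n, k=1)
    k = round_half_away(q * iu.size)
    edges = sorted(
        ((m.labels[i], m.labels[j], float(m.values[i, j]))
         for i, j in zip(iu, ju)),
        key=lambda e: (-e[2], e[0], e[1]))
    return edges[:k]
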