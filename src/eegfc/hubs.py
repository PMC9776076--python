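"""Hub detection, hub-subnetwork pathways, and the lateralized occipital
betweenness contrast.

Hubs are the nodes with the top fraction (default 30%) of betweenness
centrality values; for a 29-channel montage that is round(29 * 0.3) = 9
hubs. The strongest pathways of the hub subnetwork are the top fraction of
its connectivity weights. The lateralized contrast picks, per subject, the
occipital channel (O1 or O2) whose betweenness rose most from a baseline
stage to a task stage — operationalizing ocular dominance — and runs a
paired t-test on the chosen-channel values across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, round_half_away, top_fraction_edges
from .stats import StatResult, paired_ttest


@dataclass(frozen=True)
class HubSet:
    """The highest-betweenness nodes of one network, in descending order."""

    hubs: tuple[tuple[str, float], ...]
    fraction: float
    stage: int | None = None
    band: str | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.hubs)

    def __len__(self) -> int:
        return len(self.hubs)


@dataclass(frozen=True)
class LateralizedContrast:
    """Per-subject lateralized channel choice and the group paired t-test."""

    channels: tuple[str, ...]          # chosen channel per subject
    delta_bc: tuple[float, ...]        # BC(task) - BC(baseline), chosen channel
    test: StatResult
    degenerate: bool


def detect_hubs(bc: np.ndarray | dict[str, float],
                labels: tuple[str, ...] | None = None,
                q: float = 0.3,
                stage: int | None = None,
                band: str | None = None) -> HubSet:
    """The ``round(q * N)`` nodes with the largest betweenness.

    Ties are broken lexicographically by label so hub sets are deterministic
    and nested in ``q``.
    """
    if isinstance(bc, dict):
        labels = tuple(bc.keys())
        values = np.array([bc[l] for l in labels], dtype=float)
    else:
        values = np.asarray(bc, dtype=float)
        if labels is None:
            raise ValueError("labels required when bc is an array")
    if not 0 < q <= 1:
        raise ValueError("hub fraction must be in (0, 1]")
    if values.size != len(labels):
        raise ValueError("bc length does not match labels")
    k = round_half_away(q * len(labels))
    ranked = sorted(zip(labels, values), key=lambda t: (-t[1], t[0]))
    return HubSet(hubs=tuple((l, float(v)) for l, v in ranked[:k]),
                  fraction=q, stage=stage, band=band)


def hub_subnetwork(m: ConnectivityMatrix, hubs: HubSet) -> ConnectivityMatrix:
    """Principal submatrix of ``m`` on the hub labels (hub order preserved)."""
    missing = set(hubs.labels) - set(m.labels)
    if missing:
        raise ValueError(f"hub labels not in matrix: {sorted(missing)}")
    idx = [m.labels.index(l) for l in hubs.labels]
    return ConnectivityMatrix(labels=hubs.labels,
                              values=m.values[np.ix_(idx, idx)],
                              band=m.band, stage=m.stage,
                              normalized=m.normalized)


def hub_pathways(m: ConnectivityMatrix, hubs: HubSet, q: float = 0.3,
                 ) -> list[tuple[str, str, float]]:
    """The strongest fraction ``q`` of connections among the hubs."""
    return top_fraction_edges(hub_subnetwork(m, hubs), q=q)


def lateralized_bc_contrast(bc_task: pd.DataFrame, bc_baseline: pd.DataFrame,
                            channels: tuple[str, str] = ("O1", "O2"),
                            ) -> LateralizedContrast:
    """Occipital-lateralization contrast of betweenness between two stages.

    Parameters
    ----------
    bc_task, bc_baseline
        Subject x channel tables of betweenness for the task stage and the
        baseline stage (same index and columns).
    channels
        The candidate lateralized pair, by default the occipital (O1, O2).

    Per subject the channel with the larger betweenness increase is chosen;
    the paired t-test compares the chosen-channel values between stages
    across subjects. All-zero differences yield a flagged degenerate result
    instead of an error.
    """
    for ch in channels:
        if ch not in bc_task.columns or ch not in bc_baseline.columns:
            raise ValueError(f"channel {ch!r} missing from betweenness table")
    if not bc_task.index.equals(bc_baseline.index):
        raise ValueError("subject indices differ between stages")
    delta = bc_task[list(channels)] - bc_baseline[list(channels)]
    # argmax over the candidate pair; ties resolve to the first channel
    chosen = delta.idxmax(axis=1)
    task_vals = np.array([bc_task.at[s, c] for s, c in chosen.items()])
    base_vals = np.array([bc_baseline.at[s, c] for s, c in chosen.items()])
    test = paired_ttest(task_vals, base_vals)
    return LateralizedContrast(
        channels=tuple(chosen),
        delta_bc=tuple(float(d) for d in task_vals - base_vals),
        test=test,
        degenerate=test.degenerate,
    )
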