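"""Time-block summaries of trial-resolved connectivity.

Trials of each CS type are reordered by presentation time, evenly divided
into 4 contiguous time-blocks (block 1 = earliest), and averaged within
block.  The change quantity of interest is

    dFC = FC(block 4) - FC(block 1)

per edge and CS type; the *differential change* isolates cue-specific
dynamics as ([CS+ - CS-] at block 4) - ([CS+ - CS-] at block 1), which is
algebraically dFC(CS+) - dFC(CS-).

Edge vectors use row-major upper-triangle (i < j) order throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import Z_CAP, fisher_z, upper_edge_index, vec_upper
from .trial_fc import BetaSeries, TrialFC

__all__ = [
    "BlockFC",
    "DeltaFC",
    "block_average",
    "delta_fc",
    "differential_change",
    "component_mean_series",
    "static_fc",
]

N_BLOCKS_DEFAULT = 4


@dataclass
class BlockFC:
    """Time-block-averaged FC for one subject and CS type.

    ``blocks`` has shape (n_blocks, regions, regions); block 1 (index 0)
    averages the earliest trials.
    """

    subject_id: str
    cs_type: str
    blocks: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_regions(self) -> int:
        return self.blocks.shape[1]


@dataclass
class DeltaFC:
    """Upper-triangle edge vector of block-4 minus block-1 FC."""

    subject_id: str
    cs_type: str
    edge_vector: np.ndarray
    edge_index: list[tuple[int, int]]

    @property
    def n_regions(self) -> int:
        # length R(R-1)/2 -> R
        m = len(self.edge_vector)
        return int(round((1 + np.sqrt(1 + 8 * m)) / 2))


def block_average(tfc: TrialFC, n_blocks: int = N_BLOCKS_DEFAULT,
                  remainder: str = "error") -> dict[str, BlockFC]:
    """Average trial FC matrices into contiguous time-blocks per CS type.

    Returns a mapping cs_type -> BlockFC.  Trials of each CS type are taken
    in presentation order (row order of the trial table).  ``remainder``
    controls non-divisible trial counts: ``"error"`` (default) or
    ``"truncate-late"`` (drop the last trials).
    """
    out: dict[str, BlockFC] = {}
    cs_values = tfc.trial_table["cs_type"].astype(str).to_numpy()
    for cs in pd.unique(cs_values):
        rows = np.flatnonzero(cs_values == cs)
        n = rows.size
        if n % n_blocks != 0:
            if remainder == "truncate-late":
                rows = rows[: n - (n % n_blocks)]
            else:
                raise ValueError(
                    f"{n} {cs} trials not divisible into {n_blocks} blocks "
                    f"(remainder {n % n_blocks}); set remainder='truncate-late' "
                    f"to drop trailing trials"
                )
        per = rows.size // n_blocks
        blocks = np.stack([
            tfc.tensor[rows[b * per:(b + 1) * per]].mean(axis=0)
            for b in range(n_blocks)
        ])
        out[cs] = BlockFC(subject_id=tfc.subject_id, cs_type=cs, blocks=blocks)
    return out


def delta_fc(bfc: BlockFC) -> DeltaFC:
    """Edge vector of last-block minus first-block FC."""
    diff = bfc.blocks[-1] - bfc.blocks[0]
    return DeltaFC(
        subject_id=bfc.subject_id,
        cs_type=bfc.cs_type,
        edge_vector=vec_upper(diff),
        edge_index=upper_edge_index(bfc.n_regions),
    )


def differential_change(delta_plus: DeltaFC, delta_minus: DeltaFC) -> DeltaFC:
    """([CS+ - CS-] at block 4) - ([CS+ - CS-] at block 1), edge-wise.

    Identical to delta_fc(CS+) - delta_fc(CS-) by rearrangement.
    """
    if delta_plus.subject_id != delta_minus.subject_id:
        raise ValueError("differential change mixes subjects")
    return DeltaFC(
        subject_id=delta_plus.subject_id,
        cs_type="differential",
        edge_vector=delta_plus.edge_vector - delta_minus.edge_vector,
        edge_index=delta_plus.edge_index,
    )


def component_mean_series(bfc: BlockFC, edges) -> np.ndarray:
    """Mean FC over a component's edges, one value per time-block."""
    edges = list(edges)
    if not edges:
        raise ValueError("empty edge set")
    ii = np.array([min(e) for e in edges])
    jj = np.array([max(e) for e in edges])
    return bfc.blocks[:, ii, jj].mean(axis=1)


def static_fc(beta: BetaSeries, cs_type: str, z_cap: float = Z_CAP) -> np.ndarray:
    """Single FC matrix over all trials of one CS type (Fisher z).

    Zero-variance regions yield 0 entries (flagged by the caller via the
    returned matrix's zero rows).  Perfect correlations are capped at
    |z| = ``z_cap``.
    """
    mask = beta.trial_table["cs_type"].astype(str).to_numpy() == cs_type
    X = beta.values[mask]
    if X.shape[0] < 5:
        raise ValueError(f"need at least 5 {cs_type} trials, got {X.shape[0]}")
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    R = X.shape[1]
    out = np.zeros((R, R))
    if ok.any():
        r = np.corrcoef(X[:, ok], rowvar=False)
        z = fisher_z(r, z_cap)
        idx = np.flatnonzero(ok)
        out[np.ix_(idx, idx)] = z
    np.fill_diagonal(out, 0.0)
    return out
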