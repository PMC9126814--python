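"""Trial-resolved functional connectivity from beta series.

The central object is the *jackknife correlation*: for every trial t, the
Pearson correlation of per-trial response amplitudes (the beta series) is
computed over all trials of the phase *except* t, Fisher-transformed, and
sign-flipped, so that a trial's value reflects its own contribution to the
overall coupling of an edge.  Stacking the T leave-one-out matrices gives a
trials x regions x regions connectivity tensor — a trial-resolved FC estimate
that needs no sliding window.

Two variants are provided:

``jackknife_zflip``
    sign-flipped leave-one-out z-correlation, standardized per edge across
    trials (mean 0, SD 1).  Units are relative; downstream block differences
    are invariant to the per-edge affine rescaling.
``jackknife_pseudovalue``
    classical jackknife pseudovalues ``T*z_all - (T-1)*z_(-t)``,
    unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import Z_CAP, fisher_z

PHASES = ("conditioning", "extinction_learning", "extinction_recall")
MIN_TRIALS = 5

__all__ = [
    "BetaSeries",
    "TrialFC",
    "JackknifeConnectivity",
    "jackknife_trial_fc",
    "estimate_beta_series",
    "read_beta_series",
    "save_trial_fc",
    "load_trial_fc",
]


@dataclass
class BetaSeries:
    """Per-trial amplitude estimates for one subject and phase.

    Parameters
    ----------
    subject_id : str
    phase : str
        One of ``conditioning``, ``extinction_learning``, ``extinction_recall``.
    trial_table : pandas.DataFrame
        One row per trial in presentation order, columns ``trial`` (index),
        ``cs_type`` and ``onset`` (seconds).
    values : ndarray of shape (n_trials, n_regions)
        Amplitude estimates in arbitrary GLM units.
    region_labels : list of str, optional
    """

    subject_id: str
    phase: str
    trial_table: pd.DataFrame
    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a trials x regions matrix")
        if len(self.trial_table) != self.values.shape[0]:
            raise ValueError(
                f"trial_table has {len(self.trial_table)} rows but values has "
                f"{self.values.shape[0]} trials"
            )
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if np.isnan(self.values).any(axis=1).any():
            raise ValueError("values contains NaN rows")
        if self.region_labels is not None and len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length does not match region count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialFC:
    """Trial-resolved symmetric connectivity tensor.

    ``tensor[t]`` is the (regions x regions) jackknife connectivity matrix of
    trial ``t``; the diagonal is undefined and stored as 0.
    ``n_zero_variance`` counts edge entries that were set to 0 because a
    leave-one-out subsample had a zero-variance region.
    """

    subject_id: str
    phase: str
    method: str
    tensor: np.ndarray
    trial_table: pd.DataFrame
    n_zero_variance: int = 0

    @property
    def n_trials(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_regions(self) -> int:
        return self.tensor.shape[1]


def _loo_correlations(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All leave-one-out correlation matrices of a trials x regions matrix.

    Uses sum downdates: with S = X'X and s = column sums, removing row t
    updates both in O(R^2), so the full set costs O(T R^2) and vectorizes
    over t.  Returns (corr, zero_var_mask) where corr has shape (T, R, R)
    and zero_var_mask flags (t, i) with a degenerate leave-one-out variance.
    """
    X = np.asarray(X, dtype=float)
    T, R = X.shape
    S = X.T @ X                      # (R, R)
    s = X.sum(axis=0)                # (R,)
    n = T - 1
    s_lo = s[None, :] - X            # (T, R)
    S_lo = S[None, :, :] - X[:, :, None] * X[:, None, :]      # (T, R, R)
    cov = (S_lo - s_lo[:, :, None] * s_lo[:, None, :] / n) / (n - 1)
    var = np.einsum("tii->ti", cov).copy()
    scale = np.maximum(var, 0.0)
    # relative tolerance against the full-sample variance of each region
    full_var = X.var(axis=0, ddof=1)
    tol = full_var * 1e-9 + np.finfo(float).tiny
    zero_var = scale <= tol[None, :]
    scale[zero_var] = 1.0            # avoid division warnings; zeroed below
    d = 1.0 / np.sqrt(scale)
    corr = cov * d[:, :, None] * d[:, None, :]
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, zero_var


class JackknifeConnectivity(TransformerMixin, BaseEstimator):
    """Transform a beta-series matrix into a trial-resolved FC tensor.

    Parameters
    ----------
    method : {"jackknife_zflip", "jackknife_pseudovalue"}
        ``jackknife_zflip`` (default): sign-flipped leave-one-out
        z-correlation, standardized per edge to mean 0 / SD 1 across trials.
        ``jackknife_pseudovalue``: ``T*z_all - (T-1)*z_(-t)``, unstandardized.
    fisher : bool
        Apply the Fisher z-transform to correlations before combining
        (variance stabilization).  Default True.
    z_cap : float
        Cap on |z| so perfect correlations stay finite.
    """

    def __init__(self, method: str = "jackknife_zflip", fisher: bool = True,
                 z_cap: float = Z_CAP):
        self.method = method
        self.fisher = fisher
        self.z_cap = z_cap

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        """Compute the (T, R, R) jackknife tensor of a (T, R) matrix."""
        tensor, n_zero = self._compute(np.asarray(X, dtype=float))
        self.n_zero_variance_ = n_zero
        return tensor

    def _compute(self, X: np.ndarray) -> tuple[np.ndarray, int]:
        if self.method not in ("jackknife_zflip", "jackknife_pseudovalue"):
            raise ValueError(f"unknown method {self.method!r}")
        T, R = X.shape
        if T < MIN_TRIALS:
            raise ValueError(f"need at least {MIN_TRIALS} trials, got {T}")
        full_var = X.var(axis=0, ddof=1)
        dead = np.flatnonzero(full_var <= 0)
        if dead.size:
            raise ValueError(f"zero-variance region(s) across trials: {dead.tolist()}")

        corr, zero_var = _loo_correlations(X)
        z = fisher_z(corr, self.z_cap) if self.fisher else corr

        if self.method == "jackknife_zflip":
            out = -z
        else:
            r_all = np.corrcoef(X, rowvar=False)
            z_all = fisher_z(r_all, self.z_cap) if self.fisher else r_all
            out = T * z_all[None, :, :] - (T - 1) * z

        # zero out entries touching a degenerate leave-one-out region
        bad = zero_var[:, :, None] | zero_var[:, None, :]
        n_zero = 0
        if bad.any():
            iu = np.triu_indices(R, k=1)
            n_zero = int(bad[:, iu[0], iu[1]].sum())
            out = np.where(bad, 0.0, out)

        if self.method == "jackknife_zflip":
            mean = out.mean(axis=0, keepdims=True)
            sd = out.std(axis=0, ddof=0, keepdims=True)
            sd_safe = np.where(sd > 1e-12, sd, 1.0)
            out = np.where(sd > 1e-12, (out - mean) / sd_safe, 0.0)

        idx = np.arange(R)
        out[:, idx, idx] = 0.0
        return out, n_zero


def jackknife_trial_fc(beta: BetaSeries, method: str = "jackknife_zflip",
                       fisher: bool = True, z_cap: float = Z_CAP) -> TrialFC:
    """Trial-resolved FC for one subject's beta series (see module docstring)."""
    est = JackknifeConnectivity(method=method, fisher=fisher, z_cap=z_cap)
    tensor = est.transform(beta.values)
    return TrialFC(
        subject_id=beta.subject_id,
        phase=beta.phase,
        method=method,
        tensor=tensor,
        trial_table=beta.trial_table.copy(),
        n_zero_variance=est.n_zero_variance_,
    )


# ---------------------------------------------------------------------------
# optional GLM path: BOLD + events -> beta series (least-squares-separate)
# ---------------------------------------------------------------------------

def _region_time_series(bold, atlas) -> np.ndarray:
    """Collapse a 4-D BOLD image to a scans x regions matrix of region means."""
    import nibabel as nib

    if isinstance(bold, (str, Path)):
        bold = nib.load(str(bold))
    if hasattr(bold, "get_fdata"):
        data = np.asarray(bold.get_fdata(), dtype=float)
    else:
        data = np.asarray(bold, dtype=float)
    if data.ndim == 2:
        return data  # already scans x regions
    if data.ndim != 4:
        raise ValueError("bold must be 4-D (x, y, z, t) or 2-D (t, regions)")
    if atlas is None:
        raise ValueError("a region atlas is required for 4-D input")
    if isinstance(atlas, (str, Path)):
        atlas = nib.load(str(atlas))
    labels = np.asarray(atlas.get_fdata() if hasattr(atlas, "get_fdata") else atlas)
    labels = np.rint(labels).astype(int)
    if labels.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match the BOLD image grid")
    region_ids = np.unique(labels[labels > 0])
    n_scans = data.shape[3]
    flat = data.reshape(-1, n_scans)
    lab_flat = labels.ravel()
    out = np.empty((n_scans, region_ids.size))
    for k, rid in enumerate(region_ids):
        out[:, k] = flat[lab_flat == rid].mean(axis=0)
    return out


def _trial_regressor(onsets, durations, frame_times, hrf_model: str,
                     t_r: float) -> np.ndarray:
    from nilearn.glm.first_level import compute_regressor

    cond = np.vstack([onsets, durations, np.ones(len(onsets))])
    reg, _ = compute_regressor(cond, hrf_model, frame_times, oversampling=16)
    return reg[:, 0]


def estimate_beta_series(bold, events: pd.DataFrame, atlas=None,
                         hrf_model: str = "glover", t_r: float = 2.0,
                         drift_order: int = 2, subject_id: str = "sub-01",
                         phase: str = "extinction_learning") -> BetaSeries:
    """Estimate one amplitude per trial per region with an LSS GLM.

    For each trial a separate GLM is fit containing (a) that trial's
    HRF-convolved regressor, (b) one regressor per condition pooling all
    *other* trials, and (c) Legendre drift terms up to ``drift_order``; the
    trial's beta is its regressor's coefficient, computed on region-mean
    time series (identical to averaging voxelwise coefficients).

    ``bold`` may be a 4-D NIfTI image/array plus a label-image atlas, or a
    scans x regions matrix directly.
    """
    series = _region_time_series(bold, atlas)
    n_scans = series.shape[0]
    frame_times = np.arange(n_scans) * t_r
    events = events.reset_index(drop=True)
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    conditions = events["trial_type"].astype(str).to_numpy()
    if (onsets < 0).any() or (onsets >= n_scans * t_r).any():
        raise ValueError("event onsets fall outside the scan duration")

    # Legendre drift basis on [-1, 1]
    x = np.linspace(-1.0, 1.0, n_scans)
    drift = np.column_stack([np.polynomial.legendre.Legendre.basis(d)(x)
                             for d in range(drift_order + 1)])

    n_trials = len(events)
    betas = np.empty((n_trials, series.shape[1]))
    for i in range(n_trials):
        cols = [_trial_regressor(onsets[i:i + 1], durations[i:i + 1],
                                 frame_times, hrf_model, t_r)]
        for cond in np.unique(conditions):
            mask = (conditions == cond) & (np.arange(n_trials) != i)
            if mask.any():
                cols.append(_trial_regressor(onsets[mask], durations[mask],
                                             frame_times, hrf_model, t_r))
        design = np.column_stack(cols + [drift])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"rank-deficient LSS design for trial {i}")
        coef, *_ = np.linalg.lstsq(design, series, rcond=None)
        betas[i] = coef[0]

    table = pd.DataFrame({
        "trial": np.arange(n_trials),
        "cs_type": conditions,
        "onset": onsets,
    })
    return BetaSeries(subject_id=subject_id, phase=phase,
                      trial_table=table, values=betas)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_beta_series(beta_path, events_path, subject_id: str | None = None,
                     phase: str = "extinction_learning") -> BetaSeries:
    """Read a beta table (TSV, region columns) plus its events TSV."""
    beta_path = Path(beta_path)
    values = pd.read_csv(beta_path, sep="\t", float_precision="round_trip")
    events = pd.read_csv(events_path, sep="\t", float_precision="round_trip")
    table = pd.DataFrame({
        "trial": np.arange(len(events)),
        "cs_type": events["trial_type"].astype(str),
        "onset": events["onset"].astype(float),
    })
    if subject_id is None:
        subject_id = beta_path.stem.split("_")[0]
    return BetaSeries(subject_id=subject_id, phase=phase, trial_table=table,
                      values=values.to_numpy(dtype=float),
                      region_labels=list(values.columns))


def save_trial_fc(tfc: TrialFC, path) -> None:
    """Write a TrialFC tensor plus metadata to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=tfc.tensor, compression="gzip")
        f.attrs["subject_id"] = tfc.subject_id
        f.attrs["phase"] = tfc.phase
        f.attrs["method"] = tfc.method
        f.attrs["n_zero_variance"] = tfc.n_zero_variance
        g = f.create_group("trial_table")
        g.create_dataset("trial", data=tfc.trial_table["trial"].to_numpy(int))
        g.create_dataset("cs_type",
                         data=tfc.trial_table["cs_type"].astype(str).to_numpy(
                             dtype="S16"))
        g.create_dataset("onset", data=tfc.trial_table["onset"].to_numpy(float))


def load_trial_fc(path) -> TrialFC:
    with h5py.File(path, "r") as f:
        table = pd.DataFrame({
            "trial": f["trial_table/trial"][()],
            "cs_type": [s.decode() for s in f["trial_table/cs_type"][()]],
            "onset": f["trial_table/onset"][()],
        })
        return TrialFC(
            subject_id=str(f.attrs["subject_id"]),
            phase=str(f.attrs["phase"]),
            method=str(f.attrs["method"]),
            tensor=f["tensor"][()],
            trial_table=table,
            n_zero_variance=int(f.attrs["n_zero_variance"]),
        )
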