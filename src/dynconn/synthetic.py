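"""Synthetic cohorts with planted, group-specific connectivity dynamics.

The generator emulates the statistical structure of a two-day fear
conditioning / extinction study: during extinction learning each subject
sees interleaved CS+ and CS- trials (16 each by default); per-trial region
amplitudes (betas) are drawn from a zero-mean multivariate normal whose
correlation on a *planted* edge set ramps linearly across CS+ trials with a
group-specific slope (controls increase, patient groups stay flat or
decrease), while CS- trials keep the baseline correlation throughout.
A designated recall-phase region carries a signal linearly linked to each
subject's true connectivity change (in control groups only), and clinical
severity scores are linearly linked to it in all groups, so every
downstream stage — jackknife FC, time-block dFC, NBS, cross-phase
regression, CCA — has a recoverable ground truth.

Subject heterogeneity: each subject's slope is the group slope plus
Gaussian noise (``subject_slope_sd``), truncated to keep every trial-wise
correlation matrix positive definite.  The subject's *true dFC proxy* is
the planted-edge correlation difference between time-block 4 and
time-block 1 implied by that slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trial_fc import BetaSeries

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "default_planted_edges",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "generate_recall_edge_fc",
    "synthesize_bold",
]

CS_PLUS = "CSplus"
CS_MINUS = "CSminus"

#: clinical instruments per cohort type (anxiety cohort vs. trauma cohort)
ANXIETY_MEASURES = ("ASI", "BAI", "BDI", "STAI_T")
TRAUMA_MEASURES = ("CAPS5",)
_MEASURE_SCALE = {  # (mean, sd) on the instrument's native scale
    "ASI": (20.0, 12.0), "BAI": (12.0, 9.0), "BDI": (10.0, 8.0),
    "STAI_T": (42.0, 11.0), "CAPS5": (20.0, 15.0),
}
_ANXIETY_GROUPS = {"HC", "AX"}


def default_planted_edges(n_members: int = 8, n_spokes: int = 2):
    """A 30-edge planted component: a clique on regions 0..7 plus two
    spoke edges from region 8 to regions 0 and 1."""
    edges = [(i, j) for i in range(n_members) for j in range(i + 1, n_members)]
    edges += [(i, n_members) for i in range(n_spokes)]
    return tuple(edges)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults plant a positive CS+ slope in control groups (HC, TENC) and a
    slightly negative slope in patient groups (AX, PTSD), a recall link in
    controls only, and clinical links in all groups.
    """

    n_per_group: int = 40
    groups: tuple[str, ...] = ("HC", "AX")
    n_regions: int = 432
    n_trials_per_cs: int = 16
    planted_edges: tuple[tuple[int, int], ...] = field(
        default_factory=default_planted_edges)
    baseline_rho: float = 0.1
    slope_by_group: Mapping[str, float] = field(default_factory=lambda: {
        "HC": 0.3, "TENC": 0.3, "AX": -0.1, "PTSD": -0.1})
    subject_slope_sd: float = 0.1
    recall_link: Mapping[str, float] = field(default_factory=lambda: {
        "HC": 1.0, "TENC": 1.0, "AX": 0.0, "PTSD": 0.0})
    recall_noise_sd: float = 0.09
    clinical_link: tuple[float, ...] = (0.6, 0.6, 0.6, 0.6)
    clinical_noise_sd: float = 0.8
    recall_region: int | None = None
    trial_order: str = "alternating"   # "alternating" | "blocked" | "random"
    background_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_cs % 4 != 0:
            raise ValueError("n_trials_per_cs must be divisible by 4")
        R = self.n_regions
        for (i, j) in self.planted_edges:
            if not (0 <= i < R and 0 <= j < R) or i == j:
                raise ValueError(f"planted edge ({i},{j}) invalid for R={R}")
        if not (0 <= self.baseline_rho < 1):
            raise ValueError("baseline_rho must lie in [0, 1)")
        unknown = set(self.groups) - set(self.slope_by_group)
        if unknown:
            raise ValueError(f"no slope configured for group(s) {sorted(unknown)}")

    @property
    def planted_regions(self) -> tuple[int, ...]:
        return tuple(sorted({r for e in self.planted_edges for r in e}))

    @property
    def proxy_factor(self) -> float:
        """Maps a subject slope to its true block4-minus-block1 correlation
        change: (T - T/4) / (T - 1) for T trials in 4 equal blocks."""
        T = self.n_trials_per_cs
        return (T - T // 4) / (T - 1)


@dataclass
class SyntheticTruth:
    """Ground truth shipped with every generated cohort."""

    planted_edges: tuple[tuple[int, int], ...]
    true_slopes: dict[str, float]
    recall_slopes: dict[str, float]
    true_canonical_weights: dict[str, list[float]]
    recall_region: int
    subject_slopes: pd.Series | None = None
    subject_proxies: pd.Series | None = None


@dataclass
class Cohort:
    config: CohortConfig
    subjects: pd.DataFrame          # subject_id, group, age, sex
    betas: dict[str, BetaSeries]    # learning-phase beta series per subject
    recall: pd.DataFrame            # subject_id + one column per region
    clinical: pd.DataFrame          # subject_id + instrument columns
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# positive-definiteness of the planted one-parameter correlation family
# ---------------------------------------------------------------------------

def _safe_rho_interval(planted_edges, margin: float = 0.02):
    """Open interval of rho for which I + rho*A is positive definite,
    A being the planted adjacency restricted to planted regions."""
    regions = sorted({r for e in planted_edges for r in e})
    if not regions:
        return -0.97, 0.97
    pos = {r: k for k, r in enumerate(regions)}
    k = len(regions)
    A = np.zeros((k, k))
    for (i, j) in planted_edges:
        A[pos[i], pos[j]] = A[pos[j], pos[i]] = 1.0
    lam = np.linalg.eigvalsh(A)
    # I + rho*A is PD iff 1 + rho*lam_i > 0 for all i
    lo = -1.0 / lam[-1] if lam[-1] > 0 else -np.inf
    hi = -1.0 / lam[0] if lam[0] < 0 else np.inf
    return max(lo + margin, -0.97), min(hi - margin, 0.97)


def _validate_dynamics(config: CohortConfig) -> tuple[float, float]:
    lo, hi = _safe_rho_interval(config.planted_edges)
    T = config.n_trials_per_cs
    for g in config.groups:
        s = config.slope_by_group[g]
        for t in range(T):
            rho = config.baseline_rho + s * t / (T - 1)
            if not (lo <= rho <= hi):
                raise ValueError(
                    f"group {g}: planted correlation {rho:.3f} at CS+ trial "
                    f"{t + 1} leaves the positive-definite range "
                    f"[{lo:.3f}, {hi:.3f}]; reduce baseline_rho or the slope"
                )
    return lo, hi


def _planted_chol(planted_edges, regions, rho: float) -> np.ndarray:
    pos = {r: k for k, r in enumerate(regions)}
    k = len(regions)
    C = np.eye(k)
    for (i, j) in planted_edges:
        C[pos[i], pos[j]] = C[pos[j], pos[i]] = rho
    return np.linalg.cholesky(C)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _trial_schedule(config: CohortConfig, rng) -> list[str]:
    T = config.n_trials_per_cs
    if config.trial_order == "alternating":
        order = [CS_PLUS, CS_MINUS] * T
    elif config.trial_order == "blocked":
        order = [CS_PLUS] * T + [CS_MINUS] * T
    elif config.trial_order == "random":
        order = [CS_PLUS] * T + [CS_MINUS] * T
        order = [order[i] for i in rng.permutation(2 * T)]
    else:
        raise ValueError(f"unknown trial_order {config.trial_order!r}")
    return order


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort; identical configs give identical output."""
    lo, hi = _validate_dynamics(config)
    rng = np.random.default_rng(config.seed)
    T, R = config.n_trials_per_cs, config.n_regions
    planted_regions = config.planted_regions
    other_regions = np.setdiff1d(np.arange(R), planted_regions)
    region_labels = [f"R{r:03d}" for r in range(R)]

    rows, slopes, proxies = [], {}, {}
    betas: dict[str, BetaSeries] = {}
    recall_region = (config.recall_region if config.recall_region is not None
                     else (max(planted_regions) + 1 if planted_regions else 0))
    if recall_region >= R:
        raise ValueError("recall_region outside the atlas")

    sid_counter = 0
    for group in config.groups:
        slope_g = config.slope_by_group[group]
        for _ in range(config.n_per_group):
            sid = f"sub-{sid_counter:03d}"
            sid_counter += 1
            age = float(np.round(rng.normal(30.0, 8.0), 1))
            sex = int(rng.integers(0, 2))
            s = rng.normal(slope_g, config.subject_slope_sd)
            # keep every trial-wise correlation positive definite
            s = float(np.clip(s, lo - config.baseline_rho,
                              hi - config.baseline_rho))
            slopes[sid] = s
            proxies[sid] = s * config.proxy_factor

            order = _trial_schedule(config, rng)
            values = np.empty((2 * T, R))
            cs_plus_seen = 0
            for t_row, cs in enumerate(order):
                if cs == CS_PLUS:
                    rho = config.baseline_rho + s * cs_plus_seen / (T - 1)
                    cs_plus_seen += 1
                else:
                    rho = config.baseline_rho
                vec = np.empty(R)
                if config.background_rho > 0:
                    b = config.background_rho
                    g_fac = rng.normal()
                    vec[other_regions] = (np.sqrt(b) * g_fac +
                                          np.sqrt(1 - b) *
                                          rng.normal(size=other_regions.size))
                else:
                    vec[other_regions] = rng.normal(size=other_regions.size)
                if planted_regions:
                    L = _planted_chol(config.planted_edges, planted_regions, rho)
                    vec[list(planted_regions)] = L @ rng.normal(size=len(planted_regions))
                values[t_row] = vec

            table = pd.DataFrame({
                "trial": np.arange(2 * T),
                "cs_type": order,
                "onset": 10.0 * np.arange(2 * T),
            })
            betas[sid] = BetaSeries(subject_id=sid, phase="extinction_learning",
                                    trial_table=table, values=values,
                                    region_labels=region_labels)
            rows.append({"subject_id": sid, "group": group, "age": age,
                         "sex": sex})

    subjects = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex"])
    proxy_arr = np.array([proxies[s] for s in subjects["subject_id"]]) \
        if len(subjects) else np.array([])

    # recall-phase region table: planted link in groups with nonzero slope
    recall_cols = {f"R{r:03d}": rng.normal(0.0, config.recall_noise_sd,
                                           size=len(subjects))
                   for r in range(R)}
    recall = pd.DataFrame(recall_cols)
    if len(subjects):
        link = subjects["group"].map(dict(config.recall_link)).fillna(0.0)
        recall[f"R{recall_region:03d}"] += link.to_numpy() * proxy_arr
    recall.insert(0, "subject_id", subjects["subject_id"])

    # clinical scores: severity is standardized negative dFC proxy
    clinical = pd.DataFrame({"subject_id": subjects["subject_id"]})
    if len(subjects):
        sd = proxy_arr.std(ddof=0)
        sev = -(proxy_arr - proxy_arr.mean()) / (sd if sd > 0 else 1.0)
    else:
        sev = proxy_arr
    anx = subjects["group"].isin(_ANXIETY_GROUPS).to_numpy() \
        if len(subjects) else np.array([], dtype=bool)
    for m_idx, m in enumerate(ANXIETY_MEASURES + TRAUMA_MEASURES):
        mean, scale = _MEASURE_SCALE[m]
        w = (config.clinical_link[m_idx % len(config.clinical_link)])
        vals = mean + scale * (w * sev +
                               config.clinical_noise_sd *
                               rng.normal(size=len(subjects)))
        applicable = anx if m in ANXIETY_MEASURES else ~anx
        clinical[m] = np.where(applicable, np.round(vals, 2), np.nan)

    truth = SyntheticTruth(
        planted_edges=tuple(config.planted_edges),
        true_slopes=dict(config.slope_by_group),
        recall_slopes=dict(config.recall_link),
        true_canonical_weights={
            "delta_side": [1.0 / max(len(config.planted_edges), 1)]
                          * len(config.planted_edges),
            "clinical_side": list(config.clinical_link),
        },
        recall_region=recall_region,
        subject_slopes=pd.Series(slopes),
        subject_proxies=pd.Series(proxies),
    )
    return Cohort(config=config, subjects=subjects, betas=betas,
                  recall=recall, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# on-disk layout (BIDS-style events + delimited tables)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> Path:
    """Write a cohort as a plain-text file tree.

    Layout::

        participants.tsv                    subject_id, group, age, sex
        clinical.tsv                        subject_id + instruments
        recall.tsv                          subject_id + one column per region
        truth.json                          planted edges, slopes, weights
        sub-XXX/extinction_learning_events.tsv
        sub-XXX/extinction_learning_betas.tsv

    Beta values round-trip at full float precision through
    :func:`dynconn.trial_fc.read_beta_series` / :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(directory / "participants.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t", index=False)
    cohort.recall.to_csv(directory / "recall.tsv", sep="\t", index=False)
    truth = cohort.truth
    (directory / "truth.json").write_text(json.dumps({
        "planted_edges": [list(e) for e in truth.planted_edges],
        "true_slopes": truth.true_slopes,
        "recall_slopes": truth.recall_slopes,
        "true_canonical_weights": truth.true_canonical_weights,
        "recall_region": truth.recall_region,
        "subject_slopes": truth.subject_slopes.to_dict()
            if truth.subject_slopes is not None else {},
        "subject_proxies": truth.subject_proxies.to_dict()
            if truth.subject_proxies is not None else {},
    }, indent=1))
    for sid, beta in cohort.betas.items():
        sub_dir = directory / sid
        sub_dir.mkdir(exist_ok=True)
        events = pd.DataFrame({
            "onset": beta.trial_table["onset"],
            "duration": 6.0,
            "trial_type": beta.trial_table["cs_type"],
        })
        events.to_csv(sub_dir / "extinction_learning_events.tsv", sep="\t",
                      index=False)
        cols = beta.region_labels or [f"R{r:03d}" for r in range(beta.n_regions)]
        pd.DataFrame(beta.values, columns=cols).to_csv(
            sub_dir / "extinction_learning_betas.tsv", sep="\t", index=False)
    return directory


def read_cohort(directory) -> Cohort:
    """Read back a tree written by :func:`write_cohort` (truth included)."""
    from .trial_fc import read_beta_series

    directory = Path(directory)
    subjects = pd.read_csv(directory / "participants.tsv", sep="\t",
                           dtype={"subject_id": str})
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t",
                           dtype={"subject_id": str},
                           float_precision="round_trip")
    recall = pd.read_csv(directory / "recall.tsv", sep="\t",
                         dtype={"subject_id": str},
                         float_precision="round_trip")
    t = json.loads((directory / "truth.json").read_text())
    truth = SyntheticTruth(
        planted_edges=tuple(tuple(e) for e in t["planted_edges"]),
        true_slopes=t["true_slopes"],
        recall_slopes=t["recall_slopes"],
        true_canonical_weights=t["true_canonical_weights"],
        recall_region=t["recall_region"],
        subject_slopes=pd.Series(t["subject_slopes"], dtype=float),
        subject_proxies=pd.Series(t["subject_proxies"], dtype=float),
    )
    betas = {}
    for sid in subjects["subject_id"]:
        sub_dir = directory / sid
        betas[sid] = read_beta_series(
            sub_dir / "extinction_learning_betas.tsv",
            sub_dir / "extinction_learning_events.tsv",
            subject_id=sid, phase="extinction_learning")
    return Cohort(config=CohortConfig(n_per_group=0, groups=tuple(
                      pd.unique(subjects["group"])) if len(subjects) else ("HC",)),
                  subjects=subjects, betas=betas, recall=recall,
                  clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# auxiliary generators for cross-phase and GLM-path testing
# ---------------------------------------------------------------------------

def generate_recall_edge_fc(proxies: np.ndarray, n_edges: int, coupled_edges,
                            coupling: float, noise_sd: float = 1.0,
                            seed: int = 0) -> np.ndarray:
    """Subjects x edges recall-phase FC with a linear link to the dFC proxy
    on ``coupled_edges`` (signed ``coupling`` per proxy SD) and independent
    Gaussian noise elsewhere."""
    rng = np.random.default_rng(seed)
    proxies = np.asarray(proxies, dtype=float)
    sd = proxies.std(ddof=0)
    z = (proxies - proxies.mean()) / (sd if sd > 0 else 1.0)
    out = rng.normal(0.0, noise_sd, size=(proxies.size, n_edges))
    for e in coupled_edges:
        out[:, e] += coupling * z
    return out


def synthesize_bold(amplitudes: np.ndarray, events: pd.DataFrame,
                    t_r: float = 2.0, n_scans: int | None = None,
                    noise_sd: float = 0.0, ar_coef: float = 0.3,
                    hrf_model: str = "glover", seed: int = 0) -> np.ndarray:
    """Forward-simulate region BOLD from per-trial amplitudes.

    Each trial's boxcar is convolved with the canonical double-gamma HRF and
    scaled by that trial's amplitude per region; optional AR(1) noise is
    added.  Returns a scans x regions matrix suitable for
    :func:`dynconn.trial_fc.estimate_beta_series`.
    """
    from nilearn.glm.first_level import compute_regressor

    amplitudes = np.asarray(amplitudes, dtype=float)
    n_trials, n_regions = amplitudes.shape
    if n_scans is None:
        n_scans = int(np.ceil((events["onset"].max() + 24.0) / t_r))
    frame_times = np.arange(n_scans) * t_r
    bold = np.zeros((n_scans, n_regions))
    for i in range(n_trials):
        cond = np.array([[events["onset"].iloc[i]],
                         [events["duration"].iloc[i]], [1.0]])
        reg, _ = compute_regressor(cond, hrf_model, frame_times,
                                   oversampling=16)
        bold += reg[:, 0:1] * amplitudes[i][None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=bold.shape)
        for t in range(1, n_scans):
            eps[t] += ar_coef * eps[t - 1]
        bold += eps
    return bold
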