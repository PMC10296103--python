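"""Behavior Partial Least Squares for group-wise brain-behavior correlation.

The brain block is a participants x 152 matrix (76 regional T1 values
followed by 76 regional MD values), z-scored within each column across all
participants.  The behavior block holds three variables per participant:
strength of attractions, degree of androphilia-gynephilia (phase, degrees),
and age in months.  Participants belong to one of three groups.

The method stacks the *within-group* correlations of every behavior with
every brain column into a (groups x behaviors) x 152 cross-block matrix R
(here 9 x 152, group-major row order) and decomposes it,

    R = V S U',

into latent variables (LVs): brain saliences ``u`` (152 x L), singular
values ``s`` expressing LV strength, and behavior/group saliences ``v``
(9 x L) expressing the group contrast.  Each LV's share of cross-block
covariance is ``100 * s_i**2 / sum(s**2)``.

Inference is resampling-based:

* **Permutation test** - brain rows are permuted across the whole sample
  (behavior and group assignment fixed), the full pipeline re-run, and each
  LV's p-value is the proportion of permuted singular values meeting or
  exceeding the observed one (add-one estimator).
* **Bootstrap** - participants are resampled with replacement within group;
  each resample's (u, v) is aligned to the original axes by an orthogonal
  Procrustes rotation of the v block (guarding against axis reflection).
  The ratio of a salience to its bootstrap SE approximates a z-score; |ratio|
  >= 3 marks a stable, reliable contribution.  95% percentile CIs are formed
  for the nine brain-score-behavior correlations per LV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from . import atlas

__all__ = [
    "BEHAVIOR_COLUMNS",
    "PlsResult",
    "zscore_columns",
    "cross_block",
    "decompose",
    "brain_scores",
    "permutation_test",
    "bootstrap",
    "run_bpls",
    "stable_roi_table",
]

logger = logging.getLogger(__name__)

BEHAVIOR_COLUMNS = ("strength", "degree", "age_months")
STABILITY_THRESHOLD = 3.0


def zscore_columns(raw: np.ndarray, columns=None, ddof: int = 1) -> np.ndarray:
    """Z-score each column across all participants (rows)."""
    raw = np.asarray(raw, dtype=float)
    sd = raw.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = columns[zero[0]] if columns is not None else f"column {zero[0]}"
        raise ValueError(f"zero-variance brain column: {name}")
    return (raw - raw.mean(axis=0)) / sd


def _group_slices(group_sizes) -> list[slice]:
    edges = np.concatenate([[0], np.cumsum(group_sizes)])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _corr_rows(Xg: np.ndarray, Yg: np.ndarray) -> np.ndarray:
    """Pearson correlations of each behavior (col of Yg) with each brain col."""
    n = Xg.shape[0]
    Xc = Xg - Xg.mean(axis=0)
    Yc = Yg - Yg.mean(axis=0)
    xs = Xc.std(axis=0)
    ys = Yc.std(axis=0)
    if np.any(ys == 0):
        raise ValueError("zero-variance behavior within a group")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc.T @ Xc) / n / np.outer(ys, xs)
    return r


def cross_block(X: np.ndarray, Y: np.ndarray, group_sizes) -> np.ndarray:
    """Stacked within-group brain-behavior correlation matrix.

    Row block g (three rows) holds the correlations of group g's behaviors
    with every brain column, computed over group g's participants only;
    stacking is group-major.  Shape (3 * n_groups) x n_brain_cols.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("brain and behavior blocks have different row counts")
    blocks = []
    for sl in _group_slices(group_sizes):
        if sl.stop - sl.start < 3:
            raise ValueError("each group needs n >= 3")
        blocks.append(_corr_rows(X[sl], Y[sl]))
    return np.vstack(blocks)


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orientation: largest-|v| element of each LV positive."""
    for l in range(v.shape[1]):
        pivot = int(np.argmax(np.abs(v[:, l])))  # ties -> lowest row index
        if v[pivot, l] < 0:
            v[:, l] = -v[:, l]
            u[:, l] = -u[:, l]
    return u, v


def decompose(R: np.ndarray):
    """SVD of the cross-block matrix: R = V S U'.

    Returns (u, s, v, covariance_pct): brain saliences u (cols x L),
    non-increasing singular values s, behavior/group saliences v (rows x L),
    and each LV's percentage share of sum(s^2).
    """
    R = np.asarray(R, dtype=float)
    V, s, Ut = np.linalg.svd(R, full_matrices=False)
    u = Ut.T.copy()
    v = V.copy()
    u, v = _fix_signs(u, v)
    total = (s**2).sum()
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    return u, s, v, pct


def brain_scores(X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Project each participant's brain row onto the LV saliences: X @ u."""
    return np.asarray(X, dtype=float) @ np.asarray(u, dtype=float)


def _score_behavior_corr(X, Y, u, group_sizes) -> np.ndarray:
    """Within-group correlations of brain scores with behaviors, (9, L)."""
    scores = brain_scores(X, u)
    rows = []
    for sl in _group_slices(group_sizes):
        rows.append(_corr_rows(scores[sl], Y[sl]))  # (behaviors, L)
    return np.vstack(rows)


def permutation_test(
    X, Y, group_sizes, n_perm: int = 1000, rng=None, scheme: str = "whole_sample"
):
    """Permutation p-value for each LV's singular value.

    Brain rows are shuffled (breaking the brain-behavior link) while the
    behavior block and group assignment stay fixed; the cross-block +
    SVD pipeline is re-run per permutation.  ``scheme='within_group'``
    restricts the shuffling to within each group.  Add-one estimator:
    p_i = (#{permuted s_i >= observed s_i} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    s_obs = decompose(cross_block(X, Y, group_sizes))[1]
    exceed = np.zeros_like(s_obs)
    n = X.shape[0]
    slices = _group_slices(group_sizes)
    for _ in range(n_perm):
        if scheme == "whole_sample":
            perm = rng.permutation(n)
        elif scheme == "within_group":
            perm = np.arange(n)
            for sl in slices:
                perm[sl] = sl.start + rng.permutation(sl.stop - sl.start)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        s_perm = np.linalg.svd(cross_block(X[perm], Y, group_sizes),
                               compute_uv=False)
        exceed += s_perm >= s_obs
    return (exceed + 1) / (n_perm + 1)


def bootstrap(
    X, Y, group_sizes, n_boot: int = 1000, rng=None,
    stability_threshold: float = STABILITY_THRESHOLD, max_redraws: int = 100,
):
    """Bootstrap stability of the saliences and CIs for the correlations.

    Participants are resampled with replacement *within* group (group sizes
    preserved); each resample's (u, v) is rotated onto the original axes by
    orthogonal Procrustes on the v block before accumulating.  Returns a dict
    with ``boot_se`` (152 x L), ``boot_ratio`` (salience / SE),
    ``stable_mask`` (|ratio| >= threshold), ``corr`` (observed 9 x L
    brain-score-behavior correlations), ``corr_ci`` (9 x L x 2 percentile
    bounds) and ``n_redraws`` (degenerate resamples redrawn).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    u0, s0, v0, _ = decompose(cross_block(X, Y, group_sizes))
    corr0 = _score_behavior_corr(X, Y, u0, group_sizes)
    slices = _group_slices(group_sizes)
    u_samples = np.empty((n_boot,) + u0.shape)
    corr_samples = np.empty((n_boot,) + corr0.shape)
    n_redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = np.concatenate(
                [sl.start + rng.integers(0, sl.stop - sl.start,
                                         size=sl.stop - sl.start)
                 for sl in slices]
            )
            Yb = Y[idx]
            if all(np.ptp(Yb[sl], axis=0).min() > 0 for sl in slices):
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        Xb = X[idx]
        ub, sb, vb, _ = decompose(cross_block(Xb, Yb, group_sizes))
        rot, _ = orthogonal_procrustes(vb, v0)
        u_samples[b] = ub @ rot
        corr_samples[b] = _score_behavior_corr(Xb, Yb, ub @ rot, group_sizes)
    if n_redraws:
        logger.info("redrew %d degenerate bootstrap resamples", n_redraws)
    boot_se = u_samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        boot_ratio = np.where(boot_se > 0, u0 / boot_se, np.inf * np.sign(u0))
    corr_ci = np.stack(
        [np.percentile(corr_samples, 2.5, axis=0),
         np.percentile(corr_samples, 97.5, axis=0)], axis=-1
    )
    return {
        "boot_se": boot_se,
        "boot_ratio": boot_ratio,
        "stable_mask": np.abs(boot_ratio) >= stability_threshold,
        "corr": corr0,
        "corr_ci": corr_ci,
        "n_redraws": n_redraws,
    }


@dataclass
class PlsResult:
    """Complete behavior-PLS output for one analysis."""

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray
    covariance_pct: np.ndarray
    perm_p: np.ndarray
    brain_scores: np.ndarray
    boot_se: np.ndarray
    boot_ratio: np.ndarray
    stable_mask: np.ndarray
    corr: np.ndarray
    corr_ci: np.ndarray
    group_labels: tuple = ()
    column_names: list = field(default_factory=list)
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    def perm_p_display(self, lv: int) -> str:
        """Render p, using '< 1/(n_perm+1)' when no permutation exceeded."""
        p = self.perm_p[lv]
        floor = 1.0 / (self.n_perm + 1)
        return f"< {floor:.4g}" if p <= floor else f"{p:.3f}"

    def to_dict(self) -> dict:
        return {
            "singular_values": self.s.tolist(),
            "covariance_pct": self.covariance_pct.tolist(),
            "perm_p": self.perm_p.tolist(),
            "n_stable_per_lv": np.abs(self.stable_mask).sum(axis=0).tolist(),
            "n_perm": self.n_perm, "n_boot": self.n_boot, "seed": self.seed,
        }


def run_bpls(
    X_raw, Y, group_sizes, n_perm: int = 1000, n_boot: int = 1000,
    seed: int | None = None, column_names=None, group_labels=(),
    permutation_scheme: str = "whole_sample",
    stability_threshold: float = STABILITY_THRESHOLD,
) -> PlsResult:
    """Full behavior-PLS analysis on a raw (unscaled) brain matrix.

    Columns are z-scored across all participants, the group-stacked
    cross-block correlation matrix is decomposed, and permutation and
    bootstrap inference are run with independent substreams of ``seed``.
    """
    X = zscore_columns(X_raw, columns=column_names)
    Y = np.asarray(Y, dtype=float)
    u, s, v, pct = decompose(cross_block(X, Y, group_sizes))
    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    perm_p = permutation_test(X, Y, group_sizes, n_perm, perm_rng,
                              scheme=permutation_scheme)
    boot = bootstrap(X, Y, group_sizes, n_boot, boot_rng,
                     stability_threshold=stability_threshold)
    return PlsResult(
        u=u, s=s, v=v, covariance_pct=pct, perm_p=perm_p,
        brain_scores=brain_scores(X, u),
        boot_se=boot["boot_se"], boot_ratio=boot["boot_ratio"],
        stable_mask=boot["stable_mask"], corr=boot["corr"],
        corr_ci=boot["corr_ci"], group_labels=tuple(group_labels),
        column_names=list(column_names) if column_names is not None else [],
        n_perm=n_perm, n_boot=n_boot, seed=seed,
    )


def stable_roi_table(result: PlsResult, lv: int = 0) -> pd.DataFrame:
    """Per-region stability flags for one LV, T1 and MD side by side.

    Mirrors the conventional stable-ROI report: hemisphere, region, lobe,
    and an 'x'/'-' flag per metric, restricted to regions stable on at
    least one metric.
    """
    tab = atlas.label_table()
    n = len(tab)
    t1_stable = result.stable_mask[:n, lv]
    md_stable = result.stable_mask[n:2 * n, lv]
    out = tab.copy()
    out["T1"] = np.where(t1_stable, "x", "-")
    out["MD"] = np.where(md_stable, "x", "-")
    out["t1_boot_ratio"] = result.boot_ratio[:n, lv]
    out["md_boot_ratio"] = result.boot_ratio[n:2 * n, lv]
    return out[t1_stable | md_stable].reset_index(drop=True)


def correlation_table(result: PlsResult, lv: int = 0) -> pd.DataFrame:
    """Brain-score-behavior correlations with 95% bootstrap CIs for one LV."""
    rows = []
    groups = result.group_labels or tuple(
        f"group{i + 1}" for i in range(result.corr.shape[0] // 3)
    )
    for gi, g in enumerate(groups):
        for bi, b in enumerate(BEHAVIOR_COLUMNS):
            r = 3 * gi + bi
            lo, hi = result.corr_ci[r, lv]
            rows.append(
                {"group": g, "behavior": b, "r": result.corr[r, lv],
                 "ci_low": lo, "ci_high": hi,
                 "stable": bool(lo > 0 or hi < 0)}
            )
    return pd.DataFrame(rows)
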