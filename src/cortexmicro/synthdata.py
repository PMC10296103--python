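"""Seeded synthetic-data generators for every pipeline stage.

Three generators make the whole analysis testable without any download:

* :func:`generate_cohort` draws item-level questionnaire responses whose
  derived group moments emulate the study cohort: three groups (cisgender
  boys n=14, GD AFAB n=15, cisgender girls n=17), ages 147-216 months,
  group-dependent attraction-strength and androphilia-gynephilia (phase)
  distributions, and GIDYQ-AA scores separating cleanly around the 3.00
  screening threshold.

* :func:`generate_brain` plants a rank-1 latent brain-behavior effect,
  shared by two of the three groups, into a participants x 152 ROI table
  (76 T1 + 76 MD columns), together with a participant-level T1-MD coupling
  (shared random intercept inducing a standardized cross-metric slope).

* :func:`generate_phantom` builds small volumetric phantoms - labeled cubes
  with per-ROI positively skewed T1 distributions of known analytic mode,
  constant MD, and a sub-threshold gray-matter rind - for exercising the
  ROI extraction stage against stored truth.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import atlas, psychosex
from .roi_extract import VolumeSet

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "generate_cohort",
    "generate_brain",
    "generate_t1md_long",
    "generate_phantom",
    "default_effect_support",
]

GROUPS = ("cis_boy", "gd_afab", "cis_girl")

# Attainable limits of the attraction-vector representation
_PHASE_MIN = np.degrees(np.arccos(5 / np.hypot(5, 1)))  # ~11.31
_PHASE_MAX = np.degrees(np.arccos(1 / np.hypot(1, 5)))  # ~78.69


@dataclass
class CohortSpec:
    """Cohort-level study conditions (defaults are the study's)."""

    group_sizes: tuple = (14, 15, 17)
    #: per-group age ranges in months (uniform draw)
    age_ranges: tuple = ((147, 216), (162, 216), (152, 214))
    #: per-group strength-of-attraction (vector magnitude) mean and SD
    strength: tuple = ((3.25, 1.28), (2.98, 1.34), (2.83, 0.76))
    #: per-group degree of androphilia-gynephilia (phase, deg) mean and SD
    degree: tuple = ((64.60, 9.29), (46.99, 15.56), (30.94, 13.18))
    #: per-group GIDYQ-AA mean and SD (cis groups near ceiling, GD low)
    gidyq: tuple = ((4.91, 0.12), (2.17, 0.33), (4.90, 0.15))

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _truncnorm_meanmatched(rng, target, sd, lo, hi, size):
    """Truncated-normal draws whose *truncated* mean equals ``target``.

    Truncating N(target, sd) to [lo, hi] shifts its mean, so the location
    parameter is solved (Brent) such that the truncated mean hits the target;
    if the target is not attainable inside (lo, hi) the draw hugs the
    nearer bound.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = 8 * sd + (hi - lo)
    if target <= trunc_mean(lo - span):
        loc = lo - span
    elif target >= trunc_mean(hi + span):
        loc = hi + span
    else:
        loc = brentq(lambda m: trunc_mean(m) - target, lo - span, hi + span,
                     xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size,
                               random_state=rng)


def _items_from_latent(rng, latent, n_items):
    """1-5 item responses scattered around a latent mean.

    Each item is 1 + Binomial(4, (latent - 1) / 4), so item (and scale-mean)
    expectation equals the latent value exactly — no floor/ceiling clipping
    bias for latents near the ends of the scale.
    """
    p = np.clip((latent - 1.0) / 4.0, 0.0, 1.0)
    return 1 + rng.binomial(4, p[:, None], size=(latent.size, n_items))


def _truncnorm_group_meanmatched(rng, target, sd, lo, hi):
    """Per-element truncated normals sharing one location, group-mean-matched.

    ``lo``/``hi`` are arrays (the feasible magnitude window depends on each
    participant's phase).  A single location parameter is solved so the
    *average* truncated mean across elements equals ``target``: individuals
    whose window cannot reach the target (extreme phases force a larger
    magnitude) are compensated by the rest of the group, as a group-level
    moment target requires.
    """
    from scipy.optimize import brentq

    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)

    def group_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(np.mean(stats.truncnorm.mean(a, b, loc=loc, scale=sd)))

    span = 8 * sd + float(hi.max() - lo.min())
    left, right = lo.min() - span, hi.max() + span
    if target <= group_mean(left):
        loc = left
    elif target >= group_mean(right):
        loc = right
    else:
        loc = brentq(lambda m: group_mean(m) - target, left, right, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng)


def generate_cohort(spec: CohortSpec | None = None, seed=0):
    """Draw a synthetic cohort: scored participant table + raw item tables.

    Participant-level latent (strength, phase) pairs are drawn from
    truncated normals at the group targets and mapped back to androphilia/
    gynephilia means; item responses are then scattered around those means
    and re-scored through the questionnaire-scoring stage, so the returned
    participant table is the output of the real scoring code.

    Returns ``(participants, items)`` DataFrames.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    item_rows = []
    pid = 0
    for g, n in enumerate(spec.group_sizes):
        ages = rng.integers(spec.age_ranges[g][0], spec.age_ranges[g][1] + 1,
                            size=n)
        phase = _truncnorm_meanmatched(rng, *spec.degree[g],
                                       _PHASE_MIN, _PHASE_MAX, n)
        # magnitude limits depend on phase: (a, g) must stay inside [1,5]^2
        rad = np.radians(phase)
        m_lo = np.maximum(1 / np.cos(rad), 1 / np.sin(rad))
        m_hi = np.minimum(5 / np.cos(rad), 5 / np.sin(rad))
        mean_s, sd_s = spec.strength[g]
        mag = _truncnorm_group_meanmatched(rng, mean_s, sd_s, m_lo, m_hi)
        a = mag * np.cos(rad)
        gy = mag * np.sin(rad)
        gq = _truncnorm(rng, *spec.gidyq[g], 1.0, 5.0, n)
        a_items = _items_from_latent(rng, a, psychosex.EROS_N_ITEMS)
        g_items = _items_from_latent(rng, gy, psychosex.EROS_N_ITEMS)
        q_items = _items_from_latent(rng, gq, psychosex.GIDYQ_N_ITEMS)
        for i in range(n):
            pid += 1
            row = {"id": f"P{pid:03d}", "group": GROUPS[g],
                   "age_months": int(ages[i])}
            row.update({f"eros_a{j + 1}": a_items[i, j]
                        for j in range(psychosex.EROS_N_ITEMS)})
            row.update({f"eros_g{j + 1}": g_items[i, j]
                        for j in range(psychosex.EROS_N_ITEMS)})
            row.update({f"gidyq{j + 1}": q_items[i, j]
                        for j in range(psychosex.GIDYQ_N_ITEMS)})
            item_rows.append(row)
    items = pd.DataFrame(item_rows)
    participants = psychosex.participants_frame(psychosex.load_participants(items))
    return participants, items


def default_effect_support() -> np.ndarray:
    """Default planted-effect columns: the 38-region stable pattern.

    29 T1 columns and 9 MD columns out of the 152, chosen to mirror the
    spatial extent of the empirically stable set (left-lateralized frontal/
    parietal/temporal emphasis is not modeled; only the T1/MD split is).
    Returns signed loadings: -1 for T1 columns (shorter T1 with the
    behavioral composite), +1 for MD columns.
    """
    n = atlas.N_ROIS
    support = np.zeros(2 * n)
    support[:29] = -1.0       # 29 T1 columns
    support[n:n + 9] = +1.0   # 9 MD columns
    return support


@dataclass
class EffectSpec:
    """Planted latent brain-behavior effect and T1-MD coupling."""

    affected_groups: tuple = ("cis_boy", "gd_afab")
    #: signed loading per brain column; default = 38-column stable pattern
    loading: np.ndarray = field(default_factory=default_effect_support)
    #: effect amplitude against unit column noise; 1.0 gives a within-group
    #: brain-behavior correlation of ~0.7 on planted columns
    effect_size: float = 1.0
    #: weights of (strength, degree, age) in the behavioral composite
    behavior_weights: tuple = (1.0, 1.0, 1.0)
    noise_sd: float = 1.0
    #: standardized cross-metric (T1 -> MD) slope and its intercept ICC
    coupling_slope: float = 0.089
    coupling_icc: float = 0.5
    #: physical units: T1 mean/SD in ms, MD mean/SD in mm^2/s
    t1_scale: tuple = (1800.0, 120.0)
    md_scale: tuple = (0.0009, 8e-5)


def generate_brain(participants: pd.DataFrame, effect: EffectSpec | None = None,
                   seed=0) -> pd.DataFrame:
    """Plant the latent effect into a participants x 152 raw ROI table.

    Per column j (on the z-scale, later mapped to physical units):

    ``value_ij = sqrt(icc) * a_i + loading_j * effect_size * c_i * [i in
    affected groups] + noise``, where ``a_i`` is a participant intercept
    shared between the T1 and MD halves (scaled so the standardized T1->MD
    slope matches ``coupling_slope``) and ``c_i`` is the standardized
    behavioral composite.  Signs follow the study pattern: planted T1
    loadings are negative (shorter T1 with older age / greater gynephilia /
    stronger attractions), planted MD loadings positive.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    n = len(participants)
    n_roi = atlas.N_ROIS
    beh = participants[["strength", "degree", "age_months"]].to_numpy(float)
    z = (beh - beh.mean(axis=0)) / beh.std(axis=0, ddof=1)
    w = np.asarray(effect.behavior_weights, dtype=float)
    comp = z @ (w / np.linalg.norm(w))
    affected = participants["group"].isin(effect.affected_groups).to_numpy()

    icc, beta = effect.coupling_icc, effect.coupling_slope
    a_i = rng.normal(size=n)                      # shared participant intercept
    t1_z = (np.sqrt(icc) * a_i[:, None]
            + np.sqrt(1 - icc) * rng.normal(size=(n, n_roi)))
    # MD = beta * T1 + intercept + residual, unit marginal variance
    md_z = (beta * t1_z
            + np.sqrt(icc * (1 - beta**2)) * a_i[:, None]
            + np.sqrt((1 - icc) * (1 - beta**2)) * rng.normal(size=(n, n_roi)))
    zmat = np.hstack([t1_z, md_z]) * effect.noise_sd
    zmat += (effect.effect_size
             * np.outer(comp * affected, effect.loading))

    t1_mu, t1_sd = effect.t1_scale
    md_mu, md_sd = effect.md_scale
    phys = np.hstack(
        [t1_mu + t1_sd * zmat[:, :n_roi], md_mu + md_sd * zmat[:, n_roi:]]
    )
    out = pd.DataFrame(phys, columns=atlas.column_names())
    out.insert(0, "id", participants["id"].to_numpy())
    out.insert(1, "group", participants["group"].to_numpy())
    return out


def generate_t1md_long(n_clusters: int = 46, n_obs: int = 76,
                       slope: float = 0.089, icc: float = 0.5,
                       seed=0) -> pd.DataFrame:
    """Long-format (participant, ROI, T1, MD) data with known coupling.

    T1 is standard normal; MD = slope * T1 + intercept + residual with the
    non-slope variance 1 - slope**2 split by ``icc`` between the cluster
    intercept and the residual, so the standardized fixed slope is exactly
    ``slope``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_clusters, n_obs))
    b = rng.normal(scale=np.sqrt(icc * (1 - slope**2)), size=n_clusters)
    e = rng.normal(scale=np.sqrt((1 - icc) * (1 - slope**2)),
                   size=(n_clusters, n_obs))
    y = slope * x + b[:, None] + e
    return pd.DataFrame({
        "id": np.repeat([f"P{i:03d}" for i in range(n_clusters)], n_obs),
        "roi_id": np.tile(np.arange(1, n_obs + 1), n_clusters),
        "t1": x.ravel(),
        "md": y.ravel(),
    })


def _block_edges(total: int, parts: int) -> np.ndarray:
    sizes = np.full(parts, total // parts)
    sizes[: total % parts] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def generate_phantom(n_rois: int = 76, shape=(48, 48, 48), seed=0,
                     gm_interior: float = 0.95, gm_rind: float = 0.30):
    """Volumetric phantom: labeled blocks with known T1 modes and MD constants.

    The grid is partitioned into rectangular blocks (5 x 4 x 4 = 80, the
    first ``n_rois`` labeled 1..).  Interior voxels get gray-matter
    probability ``gm_interior``; a one-voxel rind gets ``gm_rind`` (below
    the 0.40 gate, so rind voxels must never contribute).  T1 values are
    drawn from a per-ROI gamma distribution (shape 6, scale 15 ms, per-ROI
    offset), whose analytic density mode offset + (shape-1)*scale is stored
    in the truth table; MD is constant per ROI.

    Returns ``(t1_vols, md_vols, truth)`` where the first two are
    :class:`VolumeSet` and ``truth`` is a DataFrame with the analytic
    ``t1_mode`` and ``md_value`` per ROI.
    """
    nx = 5 * 4 * 4
    if n_rois > nx:
        raise ValueError(f"grid supports at most {nx} ROIs")
    if min(shape) < 12:
        raise ValueError("grid too small for the block partition")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=int)
    gm = np.zeros(shape, dtype=float)
    t1 = np.zeros(shape, dtype=float)
    md = np.zeros(shape, dtype=float)

    ex = _block_edges(shape[0], 5)
    ey = _block_edges(shape[1], 4)
    ez = _block_edges(shape[2], 4)
    gamma_shape, gamma_scale = 6.0, 15.0
    truth_rows = []
    roi = 0
    for i in range(5):
        for j in range(4):
            for k in range(4):
                roi += 1
                if roi > n_rois:
                    break
                sl = (slice(ex[i], ex[i + 1]), slice(ey[j], ey[j + 1]),
                      slice(ez[k], ez[k + 1]))
                block_shape = tuple(s.stop - s.start for s in sl)
                labels[sl] = roi
                gm[sl] = gm_rind
                inner = tuple(slice(s.start + 1, s.stop - 1) for s in sl)
                gm[inner] = gm_interior
                offset = float(rng.uniform(800, 2200))
                t1[sl] = offset + rng.gamma(gamma_shape, gamma_scale,
                                            size=block_shape)
                md_val = float(rng.uniform(0.0006, 0.0012))
                md[sl] = md_val
                truth_rows.append({
                    "roi_id": roi,
                    "t1_mode": offset + (gamma_shape - 1) * gamma_scale,
                    "md_value": md_val,
                })
    truth = pd.DataFrame(truth_rows)
    t1_vols = VolumeSet(metric_map=t1, gm_prob_map=gm, label_map=labels)
    md_vols = VolumeSet(metric_map=md, gm_prob_map=gm, label_map=labels)
    return t1_vols, md_vols, truth
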