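"""Seeded synthetic-data generators with ground truth.

Every input the analysis pipeline consumes can be generated here with
the statistical structure the estimators assume — binomial (quantal)
release noise from the stochastic priming simulator, a roughly
seven-fold log-spread of pool sizes across synapses, Poisson miniature
event streams, and Gaussian nanoclusters blurred by localization
error.  Each generator returns its observable(s) plus a ground-truth
record mapping every generated quantity to its generating parameters,
so recovery tests never rely on hard-coded constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nanocluster import LocalizationCloud
from .quantal import DEFAULT_Q_STAR, MiniEventStream, QuantalTrain
from .simulator import (CaTransientParams, DEFAULT_CA_PARAMS,
                        PrimingModelParams, Protocol, SimState, WT_PARAMS,
                        simulate_train, simulate_train_stochastic)

__all__ = [
    "GenotypePreset",
    "WT_MINUS",
    "HK_MINUS",
    "gen_train_cohort",
    "gen_mepsc_stream",
    "ptp_rate_profile",
    "gen_az_clouds",
    "gen_hotspot_roi",
]


@dataclass(frozen=True)
class GenotypePreset:
    """Cohort-level generating regime for one genotype.

    ``frp_range`` is sampled log-uniformly per synapse (the min-max
    ratio is about seven-fold); ``sigma1_scale`` and ``k2_scale``
    multiply the base model's calcium sensitivity of ES->LS and the
    resting LS->TS rate.
    """

    name: str
    p_fusion: float
    f_ts_rest: float
    frp_range: Tuple[float, float]
    sigma1_scale: float = 1.0
    k2_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p_fusion <= 1:
            raise ValueError("p_fusion must lie in (0, 1]")
        if not 0 < self.f_ts_rest < 1:
            raise ValueError("f_ts_rest must lie in (0, 1)")
        lo, hi = self.frp_range
        if lo <= 0 or hi <= lo:
            raise ValueError("frp_range must be positive with max > min")

    def model_params(self, base: PrimingModelParams = WT_PARAMS
                     ) -> PrimingModelParams:
        """Base model parameters realizing this preset's regime."""
        p = replace(base,
                    sigma1=base.sigma1 * self.sigma1_scale,
                    k2_rest=base.k2_rest * self.k2_scale,
                    p_fusion_0=self.p_fusion)
        return p.with_f_ts(self.f_ts_rest)


WT_MINUS = GenotypePreset(name="wt/-", p_fusion=0.34, f_ts_rest=0.28,
                          frp_range=(604.0, 4609.0))
"""wt/- regime: p_fusion ~0.34, f_TS ~0.28, FRP spread ~7.6-fold."""

HK_MINUS = GenotypePreset(name="HK/-", p_fusion=0.39, f_ts_rest=0.455,
                          frp_range=(603.0, 4184.0),
                          sigma1_scale=0.15, k2_scale=2.15)
"""HK/- regime: k2_rest x2.15 shifts f_TS to ~0.46; sigma1 strongly
reduced; p_fusion ~0.39; FRP spread ~6.9-fold."""

_PRESETS = {"wt/-": WT_MINUS, "HK/-": HK_MINUS,
            "wtminus": WT_MINUS, "hkminus": HK_MINUS}


def get_preset(name: str) -> GenotypePreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")


def gen_train_cohort(preset: GenotypePreset,
                     n_synapses: int = 20,
                     freqs: Sequence[float] = (50.0, 100.0, 200.0, 333.0),
                     n_ap: int = 40,
                     seed: int = 0,
                     *,
                     noise: str = "quantal",
                     n_sweeps: int = 10,
                     amplitude_cv: float = 0.05,
                     f_ts_jitter: float = 1.4,
                     es_jitter: float = 1.3,
                     ca_params: CaTransientParams = DEFAULT_CA_PARAMS,
                     base_params: PrimingModelParams = WT_PARAMS,
                     dt: float = 2e-4,
                     ) -> Tuple[pd.DataFrame, Dict]:
    """Simulate a cohort of synapses stimulated with regular trains.

    Synapses of a genotype share the preset's kinetics and p_fusion
    but differ in their pre-stimulus pools: per synapse the FRP is
    drawn log-uniformly from the preset's range, the initial TS
    fraction is jittered log-uniformly by up to ``f_ts_jitter``-fold
    around the preset value, and the empty-site reservoir by
    ``es_jitter``-fold around its equilibrium share.  (Common kinetics
    with heterogeneous initial composition is exactly the regime the
    tensor factorization assumes; with strictly proportional pools the
    cohort tensor would be rank one and the priming-state pools could
    not be separated.)  ``noise``: "none" (mean-field), "quantal"
    (binomial release and transition sampling) or "quantal+gaussian"
    (additionally multiplicative Gaussian amplitude noise of CV
    ``amplitude_cv``).  ``n_sweeps`` stochastic repetitions per train
    are averaged (default 10), emulating the averaged mean trains of
    repeated sweeps that train analyses operate on.

    Returns a long-format table (synapse_id, genotype, f_stim_hz,
    stim_index, amplitude_pA, m) and a ground-truth dict.
    """
    if n_synapses < 1:
        raise ValueError("need n_synapses >= 1")
    if noise not in ("none", "quantal", "quantal+gaussian"):
        raise ValueError("noise must be 'none', 'quantal' or 'quantal+gaussian'")
    if f_ts_jitter < 1.0 or es_jitter < 1.0:
        raise ValueError("jitters are fold factors >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = preset.frp_range
    params = preset.model_params(base_params)
    es_share = params.resting_state().ES / params.resting_frp
    rows = []
    truth_syn = {}
    for s in range(n_synapses):
        sid = f"{preset.name}-{s:03d}"
        frp = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        jit = math.exp(rng.uniform(-math.log(f_ts_jitter),
                                   math.log(f_ts_jitter)))
        f_ts = min(0.85, max(0.05, preset.f_ts_rest * jit))
        es_jit = math.exp(rng.uniform(-math.log(es_jitter),
                                      math.log(es_jitter)))
        ts0 = f_ts * frp
        ls0 = (1.0 - f_ts) * frp
        es0 = es_jit * es_share * frp
        state0 = SimState(t=0.0, ES=es0, LS=ls0, TS=ts0, TSL=0.0, ERS=0.0,
                          p_fusion_now=params.p_fusion_0, ca_now=float("nan"))
        truth_syn[sid] = {
            "FRP": frp,
            "M_TS": ts0,
            "M_LS": ls0,
            "ES0": es0,
            "f_TS": f_ts,
            "p_fusion": preset.p_fusion,
        }
        for f in freqs:
            proto = Protocol.regular_train(f, n_ap)
            if noise == "none":
                m = simulate_train(params, ca_params, proto, dt=min(dt, 5e-4),
                                   initial_state=state0).m
            else:
                m = np.mean([simulate_train_stochastic(
                    params, ca_params, proto, seed=rng, dt=dt,
                    initial_state=state0).m for _ in range(n_sweeps)], axis=0)
            amps = m * DEFAULT_Q_STAR
            if noise == "quantal+gaussian":
                amps = amps * (1.0 + amplitude_cv * rng.standard_normal(amps.size))
            for j, a in enumerate(amps, start=1):
                rows.append((sid, "synthetic", f, j, a, a / DEFAULT_Q_STAR))
    table = pd.DataFrame(rows, columns=["synapse_id", "genotype", "f_stim_hz",
                                        "stim_index", "amplitude_pA", "m"])
    truth = {"preset": preset.name, "seed": seed, "noise": noise,
             "freqs": list(map(float, freqs)), "n_ap": n_ap,
             "q_star": DEFAULT_Q_STAR, "synapses": truth_syn}
    return table, truth


def trains_from_table(table: pd.DataFrame) -> list:
    """Long-format cohort table -> list of QuantalTrains."""
    trains = []
    for (sid, f), grp in table.groupby(["synapse_id", "f_stim_hz"], sort=True):
        grp = grp.sort_values("stim_index")
        trains.append(QuantalTrain(synapse_id=str(sid), f_stim=float(f),
                                   amplitudes=grp["amplitude_pA"].to_numpy(),
                                   genotype="synthetic"))
    return trains


def ptp_rate_profile(base_rate: float, fold: float,
                     tau: float) -> Callable[[float], float]:
    """Event-rate profile after a tetanus: the rate starts at
    ``fold * base_rate`` and relaxes to ``base_rate`` with time
    constant ``tau`` (s)."""
    if base_rate < 0 or fold < 0 or tau <= 0:
        raise ValueError("rates must be >= 0 and tau > 0")

    def rate(t: float) -> float:
        return base_rate * (1.0 + (fold - 1.0) * math.exp(-t / tau))

    return rate


def gen_mepsc_stream(rate_profile: Callable[[float], float] | float,
                     duration: float, seed: int = 0, *,
                     rate_max: Optional[float] = None,
                     amplitude_mean: float = -33.0,
                     amplitude_cv: float = 0.3,
                     ) -> Tuple[MiniEventStream, Dict]:
    """Inhomogeneous Poisson miniature-event stream by thinning.

    ``rate_profile`` is a rate function of time (Hz) or a constant;
    ``rate_max`` bounds it for the thinning proposal (inferred on a
    fine grid when omitted).  Event amplitudes are Gaussian around
    ``amplitude_mean`` (pA, negative).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if callable(rate_profile):
        fn = rate_profile
    else:
        const = float(rate_profile)
        if const < 0:
            raise ValueError("rate must be >= 0")
        fn = lambda t: const
    if rate_max is None:
        grid = np.linspace(0, duration, 2001)
        rate_max = max(fn(t) for t in grid)
    rng = np.random.default_rng(seed)
    times = []
    if rate_max > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_max)
            if t >= duration:
                break
            if rng.uniform() * rate_max <= fn(t):
                times.append(t)
    times = np.asarray(times)
    amps = amplitude_mean * (1.0 + amplitude_cv * rng.standard_normal(times.size))
    stream = MiniEventStream(event_times=times, duration=duration,
                             amplitudes=amps)
    truth = {"seed": seed, "duration": duration, "rate_max": rate_max,
             "n_events": int(times.size),
             "constant_rate": None if callable(rate_profile) else float(rate_profile)}
    return stream, truth


def _place_centers(rng: np.random.Generator, n: int, radius: float,
                   min_sep: float, z_sd: float,
                   max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample ``n`` centers in a lateral disc with minimum
    pairwise separation (relaxed if the disc is too crowded)."""
    centers = []
    sep = min_sep
    tries = 0
    while len(centers) < n:
        r = radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        cand = np.array([r * math.cos(phi), r * math.sin(phi),
                         z_sd * rng.standard_normal()])
        if all(np.linalg.norm(cand[:2] - c[:2]) >= sep for c in centers):
            centers.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                sep *= 0.8
                tries = 0
    return np.asarray(centers)


def gen_az_clouds(n_az: int = 10,
                  clusters_per_az: int = 7,
                  cluster_rg: float = 48.0,
                  bsn_clusters: int = 3,
                  bsn_rg: float = 118.0,
                  loc_error: float = 20.0,
                  clutter_density: float = 1e-8,
                  seed: int = 0,
                  *,
                  locs_per_cluster: int = 60,
                  az_radius: float = 350.0,
                  az_spacing: float = 4000.0,
                  displacement_range: Tuple[float, float] = (100.0, 300.0),
                  ) -> Tuple[LocalizationCloud, LocalizationCloud, Dict]:
    """Synthetic two-channel active-zone localization clouds.

    Each AZ carries ``bsn_clusters`` scaffold (BSN-like) nanoclusters
    and ``clusters_per_az`` release-site (Munc13-1-like) nanoclusters,
    the latter displaced laterally by 100-300 nm from a scaffold
    cluster center.  Clusters are isotropic Gaussians with per-axis SD
    r_g/sqrt(3), so the expected radius of gyration matches the
    requested value; localization error (3D RMS ``loc_error`` nm) adds
    in quadrature.  Uniform clutter of ``clutter_density`` points/nm^3
    is sprinkled over each AZ volume.  Returns (munc13_cloud,
    bsn_cloud, ground_truth).
    """
    if min(cluster_rg, bsn_rg) <= 0 or loc_error < 0:
        raise ValueError("cluster sizes must be positive, loc_error >= 0")
    rng = np.random.default_rng(seed)
    side = 2.0 * (az_radius + 3 * bsn_rg)
    vol = side * side * side

    def sample_cluster(center, rg, n):
        sd = math.sqrt((rg * rg + loc_error * loc_error) / 3.0)
        return center + sd * rng.standard_normal((n, 3))

    m_pts, m_az = [], []
    b_pts, b_az = [], []
    truth_az = {}
    lo_d, hi_d = displacement_range
    for az in range(n_az):
        origin = np.array([az * az_spacing, 0.0, 0.0])
        bsn_centers = origin + _place_centers(rng, bsn_clusters, az_radius,
                                              min_sep=2.5 * bsn_rg, z_sd=30.0)
        munc_centers = []
        guard = 0
        while len(munc_centers) < clusters_per_az:
            host = bsn_centers[rng.integers(bsn_clusters)]
            d = rng.uniform(lo_d, hi_d)
            phi = rng.uniform(0, 2 * math.pi)
            cand = host + np.array([d * math.cos(phi), d * math.sin(phi),
                                    20.0 * rng.standard_normal()])
            sep_ok = all(np.linalg.norm(cand - c) >= 3.2 * cluster_rg
                         for c in munc_centers)
            if sep_ok or guard > 500:
                munc_centers.append(cand)
                guard = 0
            else:
                guard += 1
        munc_centers = np.asarray(munc_centers)
        for c in bsn_centers:
            n = max(5, rng.poisson(locs_per_cluster))
            b_pts.append(sample_cluster(c, bsn_rg, n))
            b_az.extend([az] * n)
        for c in munc_centers:
            n = max(5, rng.poisson(locs_per_cluster))
            m_pts.append(sample_cluster(c, cluster_rg, n))
            m_az.extend([az] * n)
        n_clutter = rng.poisson(clutter_density * vol)
        if n_clutter:
            clutter = origin + rng.uniform(-side / 2, side / 2, (n_clutter, 3))
            m_pts.append(clutter)
            m_az.extend([az] * n_clutter)
        truth_az[az] = {
            "bsn_centers": bsn_centers.tolist(),
            "munc13_centers": munc_centers.tolist(),
            "n_clutter": int(n_clutter),
        }
    munc = LocalizationCloud(points=np.vstack(m_pts), channel="Munc13-1",
                             az_id=np.asarray(m_az))
    bsn = LocalizationCloud(points=np.vstack(b_pts), channel="BSN",
                            az_id=np.asarray(b_az))
    truth = {"seed": seed, "cluster_rg": cluster_rg, "bsn_rg": bsn_rg,
             "loc_error": loc_error,
             "effective_rg_munc13": math.hypot(cluster_rg, loc_error),
             "effective_rg_bsn": math.hypot(bsn_rg, loc_error),
             "clusters_per_az": clusters_per_az, "bsn_clusters": bsn_clusters,
             "displacement_range": list(displacement_range),
             "az": truth_az}
    return munc, bsn, truth


def gen_hotspot_roi(contrast: float = 6.0,
                    bright_fraction: float = 0.1,
                    seed: int = 0,
                    *,
                    shape: Tuple[int, int] = (100, 100),
                    n_background: int = 2000,
                    bg_mean: float = 100.0,
                    bg_sigma: float = 10.0,
                    dim_level: float = 2.0,
                    roi_noise: float = 0.05,
                    ) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """Synthetic ROI and background pixel intensities for hotspot
    analysis.

    Background pixels are N(bg_mean, bg_sigma).  ROI pixels sit at
    ``dim_level`` background SDs above the background mean, with a
    ``bright_fraction`` subset elevated to ``contrast`` SDs; pixel
    noise inside the ROI is ``roi_noise`` SDs (small, so the measured
    z90 tracks the bright level).  The expected enrichment
    contrast/dim_level is recorded in the ground truth.
    """
    if bg_sigma <= 0:
        raise ValueError("invalid background: bg_sigma must be positive")
    if not 0 <= bright_fraction <= 1:
        raise ValueError("bright_fraction must lie in [0, 1]")
    if contrast < dim_level:
        raise ValueError("contrast must be >= dim_level")
    rng = np.random.default_rng(seed)
    bg = bg_mean + bg_sigma * rng.standard_normal(n_background)
    n = shape[0] * shape[1]
    z_level = np.full(n, dim_level)
    n_bright = int(np.floor(bright_fraction * n))
    bright_idx = rng.choice(n, size=n_bright, replace=False)
    z_level[bright_idx] = contrast
    roi = bg_mean + bg_sigma * (z_level + roi_noise * rng.standard_normal(n))
    truth = {"seed": seed, "contrast": contrast, "dim_level": dim_level,
             "bright_fraction": bright_fraction,
             "expected_enrichment": contrast / dim_level,
             "n_bright": n_bright}
    return roi.reshape(shape), bg, truth
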