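"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access-restricted imaging data:

* two groups of ``n_per_group`` subjects with BMI drawn from the group
  distributions N(22.53, 1.37^2) (healthy weight) and N(32.55, 3.60^2)
  (non-healthy weight), truncated at the 25 kg/m^2 boundary;
* an atlas of ``n_regions`` regions (default 116) with lognormal surface
  areas and a configurable reward-system subset (thalamus / insula / putamen /
  orbitofrontal left+right by default);
* per-subject fiber records with lengths from a lognormal truncated to
  [20, 500] mm whose truncated mean is 26.2 mm; a fixed fraction of region
  pairs is never connected; planted edges receive group-shifted Poisson fiber
  counts calibrated to a requested Cohen's d on fiber density;
* ROI time series from a latent-factor model with all signal power inside the
  0.009-0.08 Hz band; for each coupling edge the target region's factor
  amplitude is modulated by a mix of the edge's (standardised) fiber density
  and fresh noise, so the across-subject correlation between edge density and
  the region's mean functional connectivity lands near ``target_r``;
* BMI as a linear combination of designated features plus Gaussian noise,
  affinely rescaled per group to the group distributions above.

All randomness flows from one root seed through named substreams
(atlas / skeleton / fibers / timeseries / bmi), so stages regenerate
independently and a cohort is bit-identical under a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import functional, structural
from .errors import InvalidSpecError
from .group_diff import HW, NON_HW
from .structural import Atlas, FiberSet, Region

# ln L ~ TruncNormal(mu, sigma) on [ln 20, ln 500]; mu solved by quadrature so
# the truncated mean is 26.2 mm.
FIBER_LOG_MEAN = 2.9074280724579142
FIBER_LOG_SD = 0.35
FIBER_LEN_MIN = 20.0
FIBER_LEN_MAX = 500.0

# Amplitude gain of the coupling injection, and the measured residual
# attenuation between the injected latent and the realised mean-FC (finite
# time series make the map latent -> mean-FC slightly noisy).  The coupling
# mix uses alpha = target_r / RHO_FC so realised correlations land on target.
COUPLING_GAIN = 0.35
RHO_FC = 0.94

_STREAMS = {"atlas": 0, "skeleton": 1, "fibers": 2, "timeseries": 3, "bmi": 4, "features": 5}

_REWARD_NAMES = [
    "Thalamus_L",
    "Thalamus_R",
    "Insula_L",
    "Insula_R",
    "Putamen_L",
    "Putamen_R",
    "Frontal_Sup_Orb_L",
    "Frontal_Sup_Orb_R",
]


def _rng(seed: int, stream: str, extra: int | None = None) -> np.random.Generator:
    entropy = [int(seed), _STREAMS[stream]]
    if extra is not None:
        entropy.append(int(extra))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort; defaults mirror the study conditions."""

    n_per_group: int = 60
    n_regions: int = 116
    bmi_mean_hw: float = 22.53
    bmi_sd_hw: float = 1.37
    bmi_mean_nhw: float = 32.55
    bmi_sd_nhw: float = 3.60
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    coupling_edges: list[tuple[tuple[int, int], int, float]] = field(default_factory=list)
    bmi_driver_features: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.87
    fiber_length_log_mean: float = FIBER_LOG_MEAN
    fiber_length_log_sd: float = FIBER_LOG_SD
    mean_fibers_per_edge: float = 6.0
    edge_sparsity: float = 0.6
    n_timepoints: int = 1200
    sampling_interval: float = 0.72
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise InvalidSpecError("n_per_group must be >= 2")
        if self.n_regions < 4:
            raise InvalidSpecError("n_regions must be >= 4")
        for sd in (self.bmi_sd_hw, self.bmi_sd_nhw, self.fiber_length_log_sd):
            if sd <= 0:
                raise InvalidSpecError("all SDs must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0 <= self.edge_sparsity <= 1:
            raise InvalidSpecError("edge_sparsity must be in [0, 1]")
        for u, v, d in self.planted_edges:
            if u == v or not np.isfinite(d):
                raise InvalidSpecError(f"bad planted edge ({u}, {v}, {d})")
        for (u, v), target, r in self.coupling_edges:
            if not -1 < r < 1:
                raise InvalidSpecError(f"target_r must be in (-1, 1), got {r}")
            if target not in (u, v):
                raise InvalidSpecError("coupling target must be an edge endpoint")
        if self.mean_fibers_per_edge <= 0:
            raise InvalidSpecError("mean_fibers_per_edge must be positive")
        if self.n_timepoints < 50:
            raise InvalidSpecError("n_timepoints must be >= 50")


@dataclass
class SubjectRecord:
    id: str
    group: str
    bmi: float
    fiber_set: FiberSet
    roi_timeseries: functional.RoiTimeSeries


@dataclass
class Cohort:
    atlas: Atlas
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise InvalidSpecError("subject ids must be unique")
        for s in self.subjects:
            want = HW if s.bmi < 25 else NON_HW
            if s.group != want:
                raise InvalidSpecError(f"subject {s.id}: group {s.group} violates BMI rule")

    @property
    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "bmi": [s.bmi for s in self.subjects],
            }
        )


def make_atlas(n_regions: int, seed: int, n_reward: int | None = None) -> Atlas:
    """Atlas with lognormal surface areas and ``n_reward`` reward-flagged
    regions placed at evenly spaced indices."""
    if n_regions < 4:
        raise InvalidSpecError("n_regions must be >= 4")
    if n_reward is None:
        n_reward = min(len(_REWARD_NAMES), n_regions // 2)
    if not 0 <= n_reward <= n_regions:
        raise InvalidSpecError("n_reward outside [0, n_regions]")
    rng = _rng(seed, "atlas")
    # typical AAL-scale cortical patch areas, ~2500 mm^2 median
    areas = np.exp(rng.normal(np.log(2500.0), 0.4, size=n_regions))
    reward_idx = {i * n_regions // n_reward for i in range(n_reward)} if n_reward else set()
    regions = []
    reward_seen = 0
    for i in range(n_regions):
        if i in reward_idx:
            name = _REWARD_NAMES[reward_seen % len(_REWARD_NAMES)]
            if reward_seen >= len(_REWARD_NAMES):
                name = f"{name}_{reward_seen}"
            regions.append(Region(i, name, float(areas[i]), True))
            reward_seen += 1
        else:
            regions.append(Region(i, f"Region_{i:03d}", float(areas[i]), False))
    return Atlas(regions)


def make_skeleton(atlas: Atlas, spec: SyntheticSpec, seed: int) -> np.ndarray:
    """Upper-triangular boolean mask of anatomically present pairs.

    A fraction ``edge_sparsity`` of pairs is never connected in any subject;
    planted and coupling edges are always present.
    """
    n = atlas.n_regions
    rng = _rng(seed, "skeleton")
    mask = np.zeros((n, n), dtype=bool)
    iu, iv = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) >= spec.edge_sparsity
    mask[iu[keep], iv[keep]] = True
    for u, v, _ in spec.planted_edges:
        mask[min(u, v), max(u, v)] = True
    for (u, v), _, _ in spec.coupling_edges:
        mask[min(u, v), max(u, v)] = True
    return mask


def _planted_rate_shift(lam0: float, d: float) -> float:
    """Poisson rate shift giving Cohen's d on counts: solves
    lam1 - lam0 = d * sqrt((lam0 + lam1) / 2)."""
    root = d / 4.0 + np.sqrt(d * d / 16.0 + lam0)
    return d * root


def _truncated_lognormal(rng: np.random.Generator, spec: SyntheticSpec, size: int) -> np.ndarray:
    mu, sd = spec.fiber_length_log_mean, spec.fiber_length_log_sd
    a = (np.log(FIBER_LEN_MIN) - mu) / sd
    b = (np.log(FIBER_LEN_MAX) - mu) / sd
    z = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)
    return np.exp(z)


def simulate_fibers(
    atlas: Atlas,
    spec: SyntheticSpec,
    subject_effect: float,
    seed: int,
    subject_id: str = "sub",
    skeleton: np.ndarray | None = None,
) -> FiberSet:
    """One subject's fiber records.

    ``subject_effect`` scales the planted group shift (0 for HW, 1 for
    non-HW).  Fiber counts per present pair are Poisson; lengths are truncated
    lognormal on [20, 500] mm.
    """
    spec.validate()
    if atlas.n_regions < 2:
        raise InvalidSpecError("atlas must contain >= 2 regions")
    if skeleton is None:
        skeleton = make_skeleton(atlas, spec, spec.seed)
    rng = _rng(seed, "fibers")
    iu, iv = np.nonzero(skeleton)
    lam = np.full(iu.size, float(spec.mean_fibers_per_edge))
    if subject_effect != 0.0:
        pair_pos = {(int(a), int(b)): j for j, (a, b) in enumerate(zip(iu, iv))}
        for u, v, d in spec.planted_edges:
            j = pair_pos.get((min(u, v), max(u, v)))
            if j is not None:  # planted edge may be absent from a caller-supplied skeleton
                lam[j] += subject_effect * _planted_rate_shift(spec.mean_fibers_per_edge, d)
    counts = rng.poisson(lam)
    region_u = np.repeat(iu, counts)
    region_v = np.repeat(iv, counts)
    lengths = _truncated_lognormal(rng, spec, int(counts.sum()))
    return FiberSet(subject_id, region_u, region_v, lengths)


def _bandlimited_noise(
    rng: np.random.Generator,
    n_timepoints: int,
    dt: float,
    n_series: int,
    f_lo: float = functional.DEFAULT_BAND[0],
    f_hi: float = functional.DEFAULT_BAND[1],
) -> np.ndarray:
    """(T, n_series) unit-variance Gaussian noise with power only in-band."""
    freqs = np.fft.rfftfreq(n_timepoints, d=dt)
    band = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    spec_re = rng.standard_normal((freqs.size, n_series))
    spec_im = rng.standard_normal((freqs.size, n_series))
    spectrum = np.where(band[:, None], spec_re + 1j * spec_im, 0.0)
    x = np.fft.irfft(spectrum, n=n_timepoints, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_timeseries(
    atlas: Atlas,
    spec: SyntheticSpec,
    structural_edge_values: pd.DataFrame,
    seed: int,
) -> dict[str, functional.RoiTimeSeries]:
    """ROI time series for every subject in ``structural_edge_values.index``.

    ``structural_edge_values``: subjects x coupling edges (columns are (u, v)
    tuples; may be empty).  Each region's signal is a shared band-limited
    factor times a per-region amplitude plus idiosyncratic band-limited noise;
    coupling-target amplitudes are modulated by the standardised edge density
    mixed with fresh noise at ``alpha = target_r / RHO_FC``.
    """
    spec.validate()
    subjects = list(structural_edge_values.index)
    n, t, dt = atlas.n_regions, spec.n_timepoints, spec.sampling_interval

    z_edges: dict[tuple[int, int], np.ndarray] = {}
    for col in structural_edge_values.columns:
        vals = structural_edge_values[col].to_numpy(dtype=float)
        vals = np.nan_to_num(vals, nan=float(np.nanmean(vals)) if np.isfinite(vals).any() else 0.0)
        sd = vals.std()
        z_edges[tuple(col)] = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

    rng = _rng(seed, "timeseries")
    out: dict[str, functional.RoiTimeSeries] = {}
    for i, sid in enumerate(subjects):
        amp = np.ones(n)
        for (u, v), target, r in spec.coupling_edges:
            key = (min(u, v), max(u, v))
            z = z_edges.get(key, np.zeros(len(subjects)))[i]
            alpha = np.clip(r / RHO_FC, -0.999, 0.999)
            mixed = alpha * z + np.sqrt(1 - alpha**2) * rng.standard_normal()
            amp[target] += COUPLING_GAIN * mixed
        amp = np.clip(amp, 0.05, None)
        g = _bandlimited_noise(rng, t, dt, 1)[:, 0]
        noise = _bandlimited_noise(rng, t, dt, n)
        values = g[:, None] * amp[None, :] + noise
        out[str(sid)] = functional.RoiTimeSeries(str(sid), values, dt)
    return out


def _phi0() -> float:
    return 1.0 / np.sqrt(2.0 * np.pi)


def map_attenuation(m1: float, s1: float, m2: float, s2: float) -> float:
    """Squared correlation between a standard-normal score and its image under
    the median-split per-group affine BMI map (closed form via half-normal
    moments).  Used to compensate the noise level so that a requested signal
    fraction f yields population R^2 ~= f."""
    c = np.sqrt(2.0 / np.pi)
    sig_h = np.sqrt(1.0 - 2.0 / np.pi)
    p0 = _phi0()
    cov = (m2 - m1) * p0 + (s1 + s2) / sig_h * (0.5 - c * p0)
    var_h = (m1**2 + s1**2 + m2**2 + s2**2) / 2.0 - ((m1 + m2) / 2.0) ** 2
    return float(cov**2 / var_h)


def noise_sd_for_signal_fraction(
    fraction: float,
    m1: float = 22.53,
    s1: float = 1.37,
    m2: float = 32.55,
    s2: float = 3.60,
) -> float:
    """Latent noise SD so the generated BMI has population R^2 ~= fraction."""
    if not 0 < fraction < 1:
        raise InvalidSpecError("signal fraction must be in (0, 1)")
    c2 = map_attenuation(m1, s1, m2, s2)
    inner = min(fraction / c2, 0.995)
    return float(np.sqrt(1.0 / inner - 1.0))


def simulate_bmi(
    features: pd.DataFrame,
    spec: SyntheticSpec,
    seed: int,
    groups: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """BMI = linear combination of driver features + Gaussian noise, affinely
    rescaled per group to the spec's group distributions.

    With ``groups=None`` the latent score's median splits the cohort; a
    pre-assigned grouping (as in :func:`generate_cohort`) is honoured instead
    when given.  Group labels always satisfy the 25 kg/m^2 rule.
    """
    spec.validate()
    ids = [fid for fid, _ in spec.bmi_driver_features]
    missing = [fid for fid in ids if fid not in features.columns]
    if missing:
        raise InvalidSpecError(f"unknown driver feature ids: {missing}")
    n = len(features)
    rng = _rng(seed, "bmi")
    if ids:
        coefs = np.array([c for _, c in spec.bmi_driver_features], dtype=float)
        s = features[ids].to_numpy(dtype=float) @ coefs
    else:
        s = np.zeros(n)
    sd = s.std()
    if sd > 0:
        s = (s - s.mean()) / sd
    total = s + rng.normal(0.0, spec.noise_sd, size=n)

    if groups is None:
        order = np.argsort(total, kind="stable")
        is_hw = np.zeros(n, dtype=bool)
        is_hw[order[: n // 2]] = True
    else:
        is_hw = np.asarray(groups) == HW

    bmi = np.empty(n)
    for mask, mean, sdev, lo, hi in (
        (is_hw, spec.bmi_mean_hw, spec.bmi_sd_hw, None, 25.0 - 1e-6),
        (~is_hw, spec.bmi_mean_nhw, spec.bmi_sd_nhw, 25.0, None),
    ):
        if not mask.any():
            continue
        tg = total[mask]
        tsd = tg.std()
        z = (tg - tg.mean()) / tsd if tsd > 0 else np.zeros_like(tg)
        vals = mean + sdev * z
        if hi is not None:
            vals = np.minimum(vals, hi)
        if lo is not None:
            vals = np.maximum(vals, lo)
        bmi[mask] = vals
    labels = np.where(bmi < 25.0, HW, NON_HW)
    return (
        pd.Series(bmi, index=features.index, name="bmi"),
        pd.Series(labels, index=features.index, name="group"),
    )


def _parse_driver_id(fid: str) -> tuple[str, tuple[int, ...]]:
    kind, _, rest = fid.partition(":")
    if kind == "sc":
        u, _, v = rest.partition("-")
        return "sc", (int(u), int(v))
    if kind == "fc":
        return "fc", (int(rest),)
    raise InvalidSpecError(f"driver feature id {fid!r} must look like 'sc:u-v' or 'fc:r'")


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Compose atlas, fibers, time series and BMI into a full cohort.

    Groups are pre-assigned (first ``n_per_group`` subjects HW) so planted
    fiber effects and the BMI rescaling see the same grouping.
    """
    spec.validate()
    seed = spec.seed
    atlas = make_atlas(spec.n_regions, seed)
    skeleton = make_skeleton(atlas, spec, seed)
    n_subj = 2 * spec.n_per_group
    subject_ids = [f"sub{i:03d}" for i in range(n_subj)]
    groups = pd.Series(
        [HW] * spec.n_per_group + [NON_HW] * spec.n_per_group, index=subject_ids, name="group"
    )

    fiber_seeds = _rng(seed, "fibers").integers(0, 2**31 - 1, size=n_subj)
    fiber_sets: dict[str, FiberSet] = {}
    networks: dict[str, structural.StructuralNetwork] = {}
    for i, sid in enumerate(subject_ids):
        effect = 0.0 if groups[sid] == HW else 1.0
        fs = simulate_fibers(
            atlas, spec, effect, int(fiber_seeds[i]), subject_id=sid, skeleton=skeleton
        )
        fiber_sets[sid] = fs
        networks[sid] = structural.build_structural_matrix(fs, atlas)

    coupling_cols = sorted({(min(u, v), max(u, v)) for (u, v), _, _ in spec.coupling_edges})
    edge_values = pd.DataFrame(
        {
            col: [
                networks[sid].density[col] if networks[sid].present[col] else np.nan
                for sid in subject_ids
            ]
            for col in coupling_cols
        },
        index=subject_ids,
    )
    if not coupling_cols:
        edge_values = pd.DataFrame(index=subject_ids)

    series = simulate_timeseries(atlas, spec, edge_values, seed)

    driver_ids = [fid for fid, _ in spec.bmi_driver_features]
    fnets = {sid: functional.correlation_matrix(series[sid]) for sid in subject_ids}
    feat_cols: dict[str, list[float]] = {}
    for fid in driver_ids:
        kind, key = _parse_driver_id(fid)
        if kind == "sc":
            u, v = min(key), max(key)
            if u < 0 or v >= atlas.n_regions:
                raise InvalidSpecError(f"driver edge {fid!r} outside atlas")
            feat_cols[fid] = [float(networks[sid].density[u, v]) for sid in subject_ids]
        else:
            (r,) = key
            if not 0 <= r < atlas.n_regions:
                raise InvalidSpecError(f"driver region {fid!r} outside atlas")
            feat_cols[fid] = [float(fnets[sid].mean_fc[r]) for sid in subject_ids]
    features = pd.DataFrame(feat_cols, index=subject_ids)

    bmi, labels = simulate_bmi(features, spec, seed, groups=groups)
    subjects = [
        SubjectRecord(sid, str(labels[sid]), float(bmi[sid]), fiber_sets[sid], series[sid])
        for sid in subject_ids
    ]
    return Cohort(atlas, subjects)


def default_spec(seed: int = 0, n_per_group: int = 60, signal_fraction: float = 0.57) -> SyntheticSpec:
    """The reference synthetic-study configuration.

    Ten planted group-different edges, each touching a reward region; six of
    them cross-modally coupled (one on a single side only, two sharing a
    reward region) with target correlations spanning 0.24-0.52; BMI driven by
    three structural and two functional features at the given signal fraction.
    """
    planted = [
        (0, 5, 1.1),
        (14, 30, 1.2),
        (14, 77, 1.0),
        (29, 40, 1.0),
        (43, 50, 1.1),
        (58, 66, 0.9),
        (72, 80, 1.2),
        (87, 95, 1.0),
        (101, 110, 1.1),
        (0, 20, 0.9),
    ]
    coupling = [
        ((0, 5), 0, 0.30),
        ((14, 30), 14, 0.26),
        ((14, 30), 30, 0.24),
        ((14, 77), 14, 0.25),
        ((14, 77), 77, 0.35),
        ((29, 40), 29, 0.25),
        ((29, 40), 40, 0.33),
        ((43, 50), 43, 0.45),
        ((43, 50), 50, 0.34),
        ((58, 66), 58, 0.44),
        ((58, 66), 66, 0.52),
    ]
    drivers = [
        ("sc:14-30", 1.0),
        ("sc:0-5", 0.8),
        ("sc:43-50", 0.7),
        ("fc:14", 0.9),
        ("fc:58", 0.6),
    ]
    return SyntheticSpec(
        n_per_group=n_per_group,
        planted_edges=planted,
        coupling_edges=coupling,
        bmi_driver_features=drivers,
        noise_sd=noise_sd_for_signal_fraction(signal_fraction),
        seed=seed,
    )


def simulate_feature_cohort(
    n_subjects: int,
    signal_fraction: float,
    seed: int,
    n_sc: int = 6,
    n_fc: int = 10,
    sc_drivers: int = 3,
    fc_drivers: int = 2,
    feature_correlation: float = 0.3,
    shared_across_modalities: bool = True,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature-level cohort for regression studies: moderately correlated
    features (latent-factor structure), BMI driven by a subset of them at the
    requested signal fraction.  Returns (features, bmi, groups).

    With ``shared_across_modalities=False`` the structural and functional
    blocks load on independent latent factors, so each modality carries
    complementary signal — the condition for studying multimodal synergy.
    Features draw from their own substream so the BMI noise (the "bmi"
    substream) stays independent of them."""
    rng = _rng(seed, "features")
    n_feat = n_sc + n_fc
    if shared_across_modalities:
        latent = np.repeat(rng.standard_normal((n_subjects, 1)), n_feat, axis=1)
    else:
        per_mod = rng.standard_normal((n_subjects, 2))
        latent = np.column_stack([per_mod[:, :1]] * n_sc + [per_mod[:, 1:]] * n_fc)
    eps = rng.standard_normal((n_subjects, n_feat))
    rho = feature_correlation
    X = np.sqrt(rho) * latent + np.sqrt(1 - rho) * eps
    names = [f"SC:f{i}" for i in range(n_sc)] + [f"FC:f{i}" for i in range(n_fc)]
    features = pd.DataFrame(X, columns=names, index=[f"sub{i:03d}" for i in range(n_subjects)])
    coef_pool = [1.0, 0.8, 0.7, 0.9, 0.6, 0.5, 0.75, 0.65]
    drivers = [(names[i], coef_pool[i % len(coef_pool)]) for i in range(sc_drivers)] + [
        (names[n_sc + i], coef_pool[(sc_drivers + i) % len(coef_pool)]) for i in range(fc_drivers)
    ]
    spec = SyntheticSpec(
        n_per_group=max(2, n_subjects // 2),
        bmi_driver_features=drivers,
        noise_sd=noise_sd_for_signal_fraction(signal_fraction),
        seed=seed,
    )
    bmi, groups = simulate_bmi(features, spec, seed)
    return features, bmi, groups
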