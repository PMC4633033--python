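"""Edge-wise group comparison of structural networks by permutation testing.

For every region pair carried by at least one subject, the fiber densities of
the subjects who have the edge are split by group (HW = BMI < 25 vs non-HW)
and compared with a pooled-variance two-sample t statistic.  Subjects lacking
the edge are excluded for that edge only; an edge is eligible for testing when
the excluded fraction stays below a threshold (default 20%) and both groups
retain at least two subjects.

Family-wise error is controlled with the single-step max-statistic permutation
procedure: group labels are shuffled once per permutation, globally for all
edges, and each edge's |t| is referred both to its own permutation null
(uncorrected p) and to the null of the maximum |t| over all eligible edges
(corrected p).  Both p-values use the add-one estimator (1 + #exceed)/(B + 1),
so the smallest reportable p is 1/(B + 1).  Per-edge subject sets are held
fixed across permutations: edge presence is anatomy, not group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError, ReferentialIntegrityError
from .structural import Atlas, StructuralNetwork

logger = logging.getLogger(__name__)

HW = "HW"
NON_HW = "nonHW"
DEFAULT_MAX_EXCLUDED = 0.20
DEFAULT_N_PERM = 5000


@dataclass
class EdgeSample:
    """Per-edge densities of the subjects carrying the edge, split by group."""

    edge: tuple[int, int]
    values_hw: np.ndarray
    values_nhw: np.ndarray
    subjects_hw: list[str]
    subjects_nhw: list[str]
    excluded_fraction: float
    eligible: bool


@dataclass
class EdgeTestResult:
    edge: tuple[int, int]
    t_stat: float
    p_uncorrected: float
    p_corrected: float
    eligible: bool = True
    reward_hit: bool = False
    sample: EdgeSample | None = field(default=None, repr=False)


def collect_edge_samples(
    networks: dict[str, StructuralNetwork],
    labels: dict[str, str],
    max_excluded: float = DEFAULT_MAX_EXCLUDED,
) -> list[EdgeSample]:
    """One EdgeSample per unordered pair present in >= 1 subject."""
    subjects = sorted(networks)
    if set(subjects) != set(labels):
        raise ReferentialIntegrityError("networks and labels cover different subjects")
    groups = np.array([labels[s] for s in subjects])
    bad = set(groups) - {HW, NON_HW}
    if bad:
        raise InvalidArgumentError(f"unknown group labels: {sorted(bad)}")
    for g in (HW, NON_HW):
        if int(np.sum(groups == g)) < 2:
            raise InvalidArgumentError(f"need >= 2 subjects in group {g}")

    density = np.stack([networks[s].density for s in subjects])  # (n_subj, n, n)
    present = np.stack([networks[s].present for s in subjects])
    n_subj, n = density.shape[0], density.shape[1]
    iu, iv = np.triu_indices(n, k=1)
    any_present = present[:, iu, iv].any(axis=0)

    samples: list[EdgeSample] = []
    is_hw = groups == HW
    subjects_arr = np.array(subjects)
    for j in np.nonzero(any_present)[0]:
        u, v = int(iu[j]), int(iv[j])
        has = present[:, u, v]
        vals = density[:, u, v]
        hw_mask = has & is_hw
        nhw_mask = has & ~is_hw
        excluded = 1.0 - has.sum() / n_subj
        eligible = excluded < max_excluded and hw_mask.sum() >= 2 and nhw_mask.sum() >= 2
        samples.append(
            EdgeSample(
                edge=(u, v),
                values_hw=vals[hw_mask],
                values_nhw=vals[nhw_mask],
                subjects_hw=list(subjects_arr[hw_mask]),
                subjects_nhw=list(subjects_arr[nhw_mask]),
                excluded_fraction=float(excluded),
                eligible=bool(eligible),
            )
        )
    return samples


def edge_statistic(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic, (a - b) orientation."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("need >= 2 values per group")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise DegenerateInputError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def _t_from_sums(n1, s1, ss1, n2, s2, ss2):
    """Vectorized pooled t from per-group counts/sums/sum-of-squares.

    Degenerate splits (a group with < 2 present subjects, or zero pooled
    variance) yield t = 0, which is conservative under the max statistic.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        sp2 = (ss1 - s1 * m1 + ss2 - s2 * m2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(t)
    return np.where(bad, 0.0, t)


def permutation_test(
    samples: list[EdgeSample],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[EdgeTestResult]:
    """Max-statistic permutation test over all eligible edge samples."""
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    eligible = [s for s in samples if s.eligible]
    if not eligible:
        logger.warning("no eligible edges to test")
        return []

    subjects = sorted({s for e in eligible for s in (*e.subjects_hw, *e.subjects_nhw)})
    idx = {s: i for i, s in enumerate(subjects)}
    n_subj, n_edge = len(subjects), len(eligible)
    X = np.zeros((n_subj, n_edge))
    M = np.zeros((n_subj, n_edge), dtype=bool)
    is_hw = np.zeros(n_subj, dtype=bool)
    for j, e in enumerate(eligible):
        for s, v in zip(e.subjects_hw, e.values_hw):
            X[idx[s], j], M[idx[s], j], is_hw[idx[s]] = v, True, True
        for s, v in zip(e.subjects_nhw, e.values_nhw):
            X[idx[s], j], M[idx[s], j] = v, True

    Xm = X * M
    X2m = Xm * X
    tot_n = M.sum(axis=0).astype(float)
    tot_s = Xm.sum(axis=0)
    tot_ss = X2m.sum(axis=0)

    def stats_for(g: np.ndarray) -> np.ndarray:
        """t per edge for label matrix g (n_lab, n_subj) with True = HW."""
        gf = g.astype(float)
        n1 = gf @ M
        s1 = gf @ Xm
        ss1 = gf @ X2m
        return _t_from_sums(n1, s1, ss1, tot_n - n1, tot_s - s1, tot_ss - ss1)

    t_obs = stats_for(is_hw[None, :])[0]

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    exceed = np.zeros(n_edge)
    exceed_max = np.zeros(n_edge)
    block = 512
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.stack([rng.permutation(is_hw) for _ in range(b)])
        t_perm = np.abs(stats_for(perms))
        exceed += (t_perm >= abs_obs[None, :]).sum(axis=0)
        exceed_max += (t_perm.max(axis=1)[:, None] >= abs_obs[None, :]).sum(axis=0)
        done += b

    p_unc = (1.0 + exceed) / (n_perm + 1.0)
    p_corr = (1.0 + exceed_max) / (n_perm + 1.0)
    p_corr = np.maximum(p_corr, p_unc)  # max-stat dominance, guard fp ties
    return [
        EdgeTestResult(
            edge=e.edge,
            t_stat=float(t_obs[j]),
            p_uncorrected=float(p_unc[j]),
            p_corrected=float(p_corr[j]),
            eligible=True,
            sample=e,
        )
        for j, e in enumerate(eligible)
    ]


def filter_reward_edges(
    results: list[EdgeTestResult],
    atlas: Atlas,
    alpha: float = 0.05,
) -> list[EdgeTestResult]:
    """Keep edges with corrected p < alpha and >= 1 reward-flagged endpoint."""
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    flags = atlas.reward_flags
    kept = []
    for r in results:
        u, v = r.edge
        if r.p_corrected < alpha and (flags[u] or flags[v]):
            r.reward_hit = True
            kept.append(r)
    return kept
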