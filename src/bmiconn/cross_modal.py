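"""Coupling of significant structural edges to functional degree centrality.

Each group-separating structural edge involves two regions; the edge's fiber
density (across subjects that carry the edge) is correlated with the mean
functional connectivity of each endpoint.  The edge is retained when either
endpoint couples at p < alpha (uncorrected by design: this screen is a plain
per-edge p < 0.05 rule, unlike the FWE-corrected group test).

The retained edges yield the prediction features: one structural feature per
retained edge, plus one functional feature per *distinct* region whose own
side of the coupling was significant -- a region shared by several retained
edges contributes a single functional feature.  For the regression design,
subjects lacking an edge contribute density 0 so the matrix has no holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .structural import Atlas

DEFAULT_ALPHA_COUPLING = 0.05


@dataclass
class CouplingRecord:
    """Correlations of one edge's density with its endpoints' mean FC."""

    edge: tuple[int, int]
    r1: float
    p1: float
    r2: float
    p2: float
    sig1: bool
    sig2: bool
    retained: bool
    alpha: float


@dataclass
class FeatureSet:
    """Subjects-by-features design matrix with provenance.

    Columns are named ``SC:<nameU>-<nameV>`` for structural edge densities and
    ``FC:<name>`` for region mean functional connectivity.
    """

    X: pd.DataFrame
    provenance: list[CouplingRecord]

    @property
    def structural_columns(self) -> list[str]:
        return [c for c in self.X.columns if c.startswith("SC:")]

    @property
    def functional_columns(self) -> list[str]:
        return [c for c in self.X.columns if c.startswith("FC:")]


def couple_edge(
    edge_densities: np.ndarray,
    mean_fc_u: np.ndarray,
    mean_fc_v: np.ndarray,
    alpha: float = DEFAULT_ALPHA_COUPLING,
    edge: tuple[int, int] = (-1, -1),
) -> CouplingRecord:
    """Pearson correlation (+ two-sided p) of edge density against each
    endpoint's mean FC over the subjects with the edge present (non-NaN)."""
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    d = np.asarray(edge_densities, dtype=float)
    fu = np.asarray(mean_fc_u, dtype=float)
    fv = np.asarray(mean_fc_v, dtype=float)
    if not (d.shape == fu.shape == fv.shape):
        raise InvalidArgumentError("subject vectors must be aligned")
    ok = np.isfinite(d)
    if ok.sum() < 4:
        raise DegenerateInputError("need >= 4 paired observations")
    r1, p1 = stats.pearsonr(d[ok], fu[ok])
    r2, p2 = stats.pearsonr(d[ok], fv[ok])
    sig1, sig2 = bool(p1 < alpha), bool(p2 < alpha)
    return CouplingRecord(
        edge=edge,
        r1=float(r1),
        p1=float(p1),
        r2=float(r2),
        p2=float(p2),
        sig1=sig1,
        sig2=sig2,
        retained=sig1 or sig2,
        alpha=alpha,
    )


def assemble_features(
    retained: list[CouplingRecord],
    densities: pd.DataFrame,
    mean_fc: pd.DataFrame,
    atlas: Atlas,
) -> FeatureSet:
    """Build the design matrix from retained coupling records.

    ``densities``: subjects x edges (columns are (u, v) tuples), NaN where the
    edge is absent -- absent entries become 0 in the design.  ``mean_fc``:
    subjects x regions (columns are region ids).
    """
    names = atlas.names
    cols: dict[str, np.ndarray] = {}
    records = [r for r in retained if r.retained]
    for rec in records:
        u, v = rec.edge
        col = f"SC:{names[u]}-{names[v]}"
        cols[col] = np.nan_to_num(densities[rec.edge].to_numpy(dtype=float), nan=0.0)
    for rec in records:
        u, v = rec.edge
        for region, sig in ((u, rec.sig1), (v, rec.sig2)):
            col = f"FC:{names[region]}"
            if sig and col not in cols:  # duplicate regions appear once
                cols[col] = mean_fc[region].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=densities.index)
    return FeatureSet(X=X, provenance=records)
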