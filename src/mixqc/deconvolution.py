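"""Deconvolution of mixture proportions from genome-scale signals.

Given the pure-component profile and the measured (linear-scale) mixture
signals, the mixing model is inverted: for each mixture, find the
fraction vector phi on the probability simplex minimizing the sum of
squared differences between measured signals and the phi-weighted
combination of pure means.  The solver enumerates the faces of the
simplex (support sets), solves the sum-to-one equality-constrained
least-squares problem on each via its KKT system, and keeps the feasible
minimum — exact for this convex problem at the small component counts of
mixture designs.

The target-plot geometry summarizes accuracy: for each component, the
point (phi_hat in Mix1, phi_hat in Mix2) is compared to the designed
point, and the Euclidean segment lengths (and their sum) indicate bias.
Uncertainty ellipses come from bootstrap resampling of miRNA rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import MixtureDesign
from .ingest import ExpressionTable
from .selectivity import PureProfile

__all__ = [
    "ProportionEstimate",
    "ComponentEllipse",
    "ProportionUncertainty",
    "TargetGeometry",
    "estimate_proportions",
    "proportion_uncertainty",
    "target_geometry",
    "solve_simplex_lstsq",
]

_MAX_ENUM_COMPONENTS = 12


def solve_simplex_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimize ||A x - b||^2 subject to x >= 0 and sum(x) = 1.

    Exact face enumeration: for every nonempty support set F, solve the
    equality-constrained least squares on F through the KKT system and
    keep the feasible solution with the smallest residual.  The global
    optimum lies in the relative interior of some face, where the
    equality-constrained solution is feasible, so the enumeration finds
    it exactly.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n, k = A.shape
    if k > _MAX_ENUM_COMPONENTS:
        raise ValueError(f"face enumeration supports at most {_MAX_ENUM_COMPONENTS} components")
    best_obj = np.inf
    best_x: Optional[np.ndarray] = None
    for size in range(1, k + 1):
        for F in itertools.combinations(range(k), size):
            AF = A[:, F]
            G = AF.T @ AF
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * G
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * AF.T @ b, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            xF = sol[:size]
            if np.any(xF < -1e-10):
                continue
            x = np.zeros(k)
            x[list(F)] = np.clip(xF, 0.0, None)
            x /= x.sum()
            obj = float(np.sum((A @ x - b) ** 2))
            if best_x is None or obj < best_obj:
                best_obj = obj
                best_x = x
    if best_x is None:
        raise RuntimeError("simplex least squares failed on every face")
    return best_x


@dataclass
class ProportionEstimate:
    """Estimated mixture fractions and target-plot segment summary.

    ``phi_hat`` is component x mixture (columns sum to 1).  For
    two-mixture designs, ``segment_length[c]`` is the Euclidean distance
    in (phi in Mix1, phi in Mix2) space between the designed and
    estimated points for component c, and ``length_sum`` their total — a
    single indicator of proportion bias.
    """

    phi_hat: pd.DataFrame
    design: MixtureDesign
    segment_length: Optional[pd.Series] = None
    length_sum: Optional[float] = None
    n_mirna: int = 0


def _mixture_means(
    mixtures: Union[ExpressionTable, pd.DataFrame], design: MixtureDesign
) -> pd.DataFrame:
    """Average replicate columns per mixture on the linear scale."""
    if isinstance(mixtures, pd.DataFrame):
        missing = [m for m in design.mixture_ids if m not in mixtures.columns]
        if missing:
            raise ValueError(f"mixture means lack columns: {missing}")
        return mixtures[list(design.mixture_ids)]
    cols = {}
    for m in design.mixture_ids:
        ids = mixtures.manifest.samples_for_role(f"mix:{m}")
        if not ids:
            raise ValueError(f"no samples for mixture {m!r}")
        cols[m] = mixtures.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def _check_profile_rank(A: np.ndarray) -> None:
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"need at least {A.shape[1]} miRNA rows, got {A.shape[0]}"
        )
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(
            f"pure-component profile is rank deficient (condition number {cond:.3g}); "
            "tissue columns are collinear"
        )


def estimate_proportions(
    profile: PureProfile,
    mixtures: Union[ExpressionTable, pd.DataFrame],
    design: MixtureDesign,
) -> ProportionEstimate:
    """Constrained least-squares fit of the mixing fractions.

    ``mixtures`` is either a linear-scale expression table whose manifest
    identifies the mixture replicates (averaged per mixture), or a
    DataFrame of per-mixture linear mean signals.  Rows are aligned with
    the profile by miRNA id; all shared detected miRNAs enter the fit.
    """
    means = _mixture_means(mixtures, design)
    common = profile.linear_means.index.intersection(means.index)
    A = profile.linear_means.loc[common, list(design.component_ids)].to_numpy(float)
    _check_profile_rank(A)
    phi_hat = np.column_stack(
        [
            solve_simplex_lstsq(A, means.loc[common, m].to_numpy(float))
            for m in design.mixture_ids
        ]
    )
    est = ProportionEstimate(
        phi_hat=pd.DataFrame(
            phi_hat, index=list(design.component_ids), columns=list(design.mixture_ids)
        ),
        design=design,
        n_mirna=len(common),
    )
    if design.n_mixtures == 2:
        geom = target_geometry(design, est)
        est.segment_length = geom.lengths
        est.length_sum = geom.length_sum
    return est


@dataclass
class ComponentEllipse:
    """95% bootstrap confidence ellipse of one component's (Mix1, Mix2) fractions."""

    center: np.ndarray  # bootstrap mean of (phi_hat in Mix1, Mix2)
    cov: np.ndarray  # 2x2 bootstrap covariance
    chi2_quantile: float
    degenerate: bool

    def contains(self, point: np.ndarray) -> bool:
        d = np.asarray(point, dtype=float) - self.center
        try:
            md2 = float(d @ np.linalg.solve(self.cov, d))
        except np.linalg.LinAlgError:
            return False
        return md2 <= self.chi2_quantile


@dataclass
class ProportionUncertainty:
    ellipses: dict[str, ComponentEllipse]
    n_boot: int
    confidence: float
    boot_estimates: Optional[np.ndarray] = None  # n_boot x components x mixtures


def proportion_uncertainty(
    profile: PureProfile,
    mixtures: Union[ExpressionTable, pd.DataFrame],
    design: MixtureDesign,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    confidence: float = 0.95,
    keep_draws: bool = False,
) -> ProportionUncertainty:
    """Bootstrap (over miRNA rows) confidence ellipses for the fractions.

    Rows are resampled with replacement, the simplex fit repeated, and
    each component's 2D (Mix1, Mix2) empirical covariance turned into a
    chi-square(2 df) contour centered at the bootstrap mean.  With
    noise-free data the resampling variance collapses and the ellipse
    degenerates to (near) a point or segment; that is flagged.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10 for a usable ellipse")
    if design.n_mixtures != 2:
        raise ValueError("confidence ellipses are defined for 2-mixture designs")
    est = estimate_proportions(profile, mixtures, design)
    means = _mixture_means(mixtures, design)
    common = profile.linear_means.index.intersection(means.index)
    A = profile.linear_means.loc[common, list(design.component_ids)].to_numpy(float)
    B = means.loc[common, list(design.mixture_ids)].to_numpy(float)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    draws = np.empty((n_boot, design.n_components, 2))
    for t in range(n_boot):
        idx = rng.integers(0, n, size=n)
        for j in range(2):
            try:
                draws[t, :, j] = solve_simplex_lstsq(A[idx], B[idx, j])
            except (ValueError, RuntimeError):
                draws[t, :, j] = np.nan
    q = float(stats.chi2.ppf(confidence, df=2))
    ellipses = {}
    for i, comp in enumerate(design.component_ids):
        pts = draws[:, i, :]
        pts = pts[~np.isnan(pts).any(axis=1)]
        cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
        cov = np.atleast_2d(cov)
        eig = np.linalg.eigvalsh(cov)
        degenerate = bool(eig.min() <= 1e-18)
        center = (
            pts.mean(axis=0) if len(pts) else est.phi_hat.loc[comp].to_numpy(float)
        )
        ellipses[comp] = ComponentEllipse(
            center=center,
            cov=cov,
            chi2_quantile=q,
            degenerate=degenerate,
        )
    return ProportionUncertainty(
        ellipses=ellipses,
        n_boot=n_boot,
        confidence=confidence,
        boot_estimates=draws if keep_draws else None,
    )


@dataclass
class TargetGeometry:
    """Target-plot geometry: designed centers, estimated endpoints, segments."""

    centers: pd.DataFrame  # component x (x, y) designed fractions
    endpoints: pd.DataFrame  # component x (x, y) estimated fractions
    lengths: pd.Series
    length_sum: float


def target_geometry(design: MixtureDesign, estimate: ProportionEstimate) -> TargetGeometry:
    """Segment geometry in (fraction-in-Mix1, fraction-in-Mix2) space.

    Per component the center is the designed point, the endpoint the
    estimated point, the segment length their Euclidean distance; the sum
    of lengths is the single-number proportion-bias indicator.
    """
    if design.n_mixtures != 2:
        raise ValueError("target plots are defined for 2-mixture designs")
    comps = list(design.component_ids)
    centers = pd.DataFrame(design.phi, index=comps, columns=["x", "y"])
    endpoints = pd.DataFrame(
        estimate.phi_hat[list(design.mixture_ids)].to_numpy(),
        index=comps,
        columns=["x", "y"],
    )
    lengths = pd.Series(
        np.linalg.norm(endpoints.to_numpy() - centers.to_numpy(), axis=1), index=comps
    )
    return TargetGeometry(
        centers=centers,
        endpoints=endpoints,
        lengths=lengths,
        length_sum=float(lengths.sum()),
    )
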