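"""Synthetic reference-sample datasets with known ground truth.

Emulates the three-tissue reference set: each tissue profile spans a wide
dynamic range (log-normal baseline abundances) and carries a designed
subset of tissue-selective miRNAs (enriched ``enrichment_fold``-fold in
one tissue), a designed brain=placenta subset, and ordinary miRNAs whose
brain/placenta log2 ratio is kept outside the equality band so the
designed class labels are unambiguous.  Mixture samples are generated
from the ground-truth linear signals through the linear mixing equations
and platform noise is applied on top:

- ``ngs``: a multinomial draw of ``depth`` total reads over the miRNA
  proportions per sample (compositional, like sequencing);
- ``hyb``: signal plus an additive background floor times multiplicative
  log-normal noise (additive background produces the ratio compression
  characteristic of hybridization at low abundance);
- ``pcr``: Cq = intercept - log2(signal) + Gaussian noise.

By default the tissue columns are rescaled to exactly equal totals (equal
miRNA mass fraction per unit total RNA — the ideal the median-total
normalization assumes), with the brain=placenta equalities re-imposed
exactly; under this default the designed labels coincide exactly with
``classify_selectivity`` on the noise-free profile and the noise-free
pipeline recovers the design perfectly.  Per-tissue ``mirna_fraction``
scalars can break the ideal deliberately to reproduce the consistent
proportion-bias segments real tissues show.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import MixtureDesign, build_manifest, make_default_design
from .ingest import ExpressionTable
from .selectivity import PureProfile, SelectivityClassification, classify_selectivity

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_pure_profiles", "simulate_dataset"]

_TISSUES = ("liver", "brain", "placenta")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic reference-sample generator.

    Defaults mirror a well-powered sequencing site: ~1000 detected
    miRNAs of which roughly 9.5% are brain-selective, 9.5% placenta-
    selective, 2% liver-selective and 3% designed brain=placenta, a
    log-normal abundance distribution wide enough to span ~15-20 log2
    units, 3 replicates of each of the 5 samples, and 2 million reads per
    sample.
    """

    n_mirna: int = 1000
    frac_selective: Mapping[str, float] = field(
        default_factory=lambda: {"liver": 0.02, "brain": 0.095, "placenta": 0.095}
    )
    frac_equal_pair: float = 0.032
    enrichment_fold: float = 30.0
    abundance_log2_mean: float = 6.0
    abundance_log2_sd: float = 3.0
    liver_log2_jitter: float = 1.0
    bp_log2_gap: tuple[float, float] = (0.7, 2.0)
    platform: str = "ngs"  # ngs | hyb | pcr
    depth: Optional[int] = 2_000_000  # ngs reads/sample; None = noise-free expected signals
    background: float = 0.0  # hyb additive floor
    hyb_noise_sd: float = 0.25  # hyb multiplicative noise, log2 sd
    cq_intercept: float = 40.0
    cq_noise_sd: float = 0.25
    mirna_fraction: Optional[Mapping[str, float]] = None  # per-tissue total-signal scalars
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 10:
            raise ValueError("n_mirna must be at least 10")
        if self.enrichment_fold < 10:
            raise ValueError("enrichment_fold must be >= 10 (the selectivity rule)")
        total = sum(self.frac_selective.values()) + self.frac_equal_pair
        if total > 1:
            raise ValueError("selective + equal-pair fractions exceed 1")
        if set(self.frac_selective) - set(_TISSUES):
            raise ValueError(f"frac_selective keys must be among {_TISSUES}")
        if self.platform not in ("ngs", "hyb", "pcr"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.bp_log2_gap[0] <= 0.5:
            raise ValueError(
                "bp_log2_gap must start above the 0.5 log2 equality band, "
                "otherwise designed labels are ambiguous"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimulatedDataset:
    table: ExpressionTable
    truth_profile: PureProfile
    truth_labels: SelectivityClassification
    design: MixtureDesign
    config: SimulationConfig

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth record."""
        cfg = asdict(self.config)
        cfg["frac_selective"] = dict(self.config.frac_selective)
        if self.config.mirna_fraction is not None:
            cfg["mirna_fraction"] = dict(self.config.mirna_fraction)
        return {
            "phi": self.design.to_dict(),
            "labels": self.truth_labels.class_of.to_dict(),
            "subtypes": self.truth_labels.subtype_of.to_dict(),
            "config": cfg,
        }


def _equalize_columns_iterative(
    values: np.ndarray, equal_rows: np.ndarray, target: float
) -> np.ndarray:
    """Alternate column rescaling with re-imposing brain == placenta.

    Generic fallback when the group-factor solve is degenerate (e.g. no
    designed subsets).  Converges fast because the equal-row mass is a
    small share of each column.
    """
    out = values.copy()
    for _ in range(500):
        out *= target / out.sum(axis=0, keepdims=True)
        out[equal_rows, 2] = out[equal_rows, 1]
        totals = out.sum(axis=0)
        if np.max(np.abs(totals - target)) <= 1e-12 * target:
            break
    out *= target / out.sum(axis=0, keepdims=True)
    out[equal_rows, 2] = out[equal_rows, 1]
    return out


def _equalize_totals(
    values: np.ndarray, groups: list[np.ndarray], equal_rows: np.ndarray
) -> np.ndarray:
    """Rescale row groups so the three column totals are exactly equal.

    Scaling a whole row preserves every within-row cross-tissue ratio, so
    the designed selectivity structure survives untouched; choosing one
    multiplicative factor per designed group (liver/brain/placenta-
    selective, equal-pair, rest) gives enough freedom to equalize column
    totals exactly.  Factors are the minimum-norm deviation from 1
    satisfying the total constraints, projected into the strictly
    positive region when needed; when the group structure is degenerate
    (too few groups) the iterative column-scaling fallback is used.
    """
    masks = [g for g in groups if g.any()]
    C = np.column_stack([values[g].sum(axis=0) for g in masks])  # 3 x n_groups
    target = float(C.sum(axis=1).mean())
    b = np.full(3, target)
    ones = np.ones(C.shape[1])
    alpha = None
    if C.shape[1] >= 3 and np.linalg.matrix_rank(C) == 3:
        alpha = ones + C.T @ np.linalg.solve(C @ C.T, b - C @ ones)
        if not np.all(alpha > 0):
            from scipy.optimize import minimize

            # closest strictly positive factors satisfying the constraints
            res = minimize(
                lambda a: np.sum((a - 1.0) ** 2),
                np.full(C.shape[1], 1.0),
                jac=lambda a: 2.0 * (a - 1.0),
                constraints=[{"type": "eq", "fun": lambda a: (C @ a - b) / target,
                              "jac": lambda a: C / target}],
                bounds=[(0.05, None)] * C.shape[1],
                method="SLSQP",
                options={"maxiter": 200, "ftol": 1e-14},
            )
            if res.success:
                # one exact min-norm correction step from the SLSQP point;
                # the step is tiny so positivity is preserved
                alpha = res.x + C.T @ np.linalg.solve(C @ C.T, b - C @ res.x)
            else:
                alpha = None
    if alpha is not None and (
        np.max(np.abs(C @ alpha - b)) > 1e-6 * target or np.any(alpha <= 0)
    ):
        alpha = None
    if alpha is None:
        out = _equalize_columns_iterative(values, equal_rows, target)
    else:
        out = values.copy()
        for g, a in zip(masks, alpha):
            out[g] *= a
        # exact equality to machine precision
        out *= target / out.sum(axis=0, keepdims=True)
    totals = out.sum(axis=0)
    if np.max(np.abs(totals - target)) > 1e-9 * target:
        raise RuntimeError("could not equalize tissue totals")
    return out


def simulate_pure_profiles(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[PureProfile, SelectivityClassification]:
    """Draw ground-truth tissue profiles and their designed class labels.

    Baseline abundances are log-normal; designated selective miRNAs get
    their target tissue multiplied by ``enrichment_fold`` (satisfying the
    >= 10x rule exactly at the noise-free level); designated
    brain=placenta miRNAs get exactly equal signal in those tissues;
    every remaining miRNA's brain/placenta log2 gap is drawn outside
    (above) the equality band.  The emitted labels provably agree with
    ``classify_selectivity`` on the returned noise-free profile.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_mirna
    base = 2.0 ** rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, n)

    # disjoint designed subsets
    order = rng.permutation(n)
    sizes = {t: int(round(config.frac_selective.get(t, 0.0) * n)) for t in _TISSUES}
    n_eq = int(round(config.frac_equal_pair * n))
    pos = 0
    sel_idx: dict[str, np.ndarray] = {}
    for t in _TISSUES:
        sel_idx[t] = order[pos : pos + sizes[t]]
        pos += sizes[t]
    eq_idx = order[pos : pos + n_eq]
    pos += n_eq
    rest_idx = order[pos:]

    vals = np.empty((n, 3))
    liver_jit = 2.0 ** rng.uniform(-config.liver_log2_jitter, config.liver_log2_jitter, n)
    gap_lo, gap_hi = config.bp_log2_gap
    gap = rng.uniform(gap_lo, gap_hi, n) * rng.choice([-1.0, 1.0], n)
    vals[:, 0] = base * liver_jit
    vals[:, 1] = base * 2.0 ** (gap / 2.0)
    vals[:, 2] = base * 2.0 ** (-gap / 2.0)

    # selective rows: equal baseline everywhere, target tissue enriched.
    # Brain == placenta on liver-selective rows makes them exact designed
    # true negatives (predicted M = 0) under any column scaling.
    for j, t in enumerate(_TISSUES):
        idx = sel_idx[t]
        vals[idx, :] = base[idx, None]
        vals[idx, j] *= config.enrichment_fold
    vals[eq_idx, :] = base[eq_idx, None]
    vals[eq_idx, 0] = base[eq_idx] * liver_jit[eq_idx]

    def _mask(idx: np.ndarray) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        m[idx] = True
        return m

    equal_rows = _mask(eq_idx) | _mask(sel_idx["liver"])
    vals = _equalize_totals(
        vals,
        [_mask(sel_idx[t]) for t in _TISSUES] + [_mask(eq_idx), _mask(rest_idx)],
        equal_rows,
    )
    if config.mirna_fraction is not None:
        for j, t in enumerate(_TISSUES):
            vals[:, j] *= float(config.mirna_fraction.get(t, 1.0))

    ids = [f"mir-{i:04d}" for i in range(n)]
    profile = PureProfile(pd.DataFrame(vals, index=ids, columns=list(_TISSUES)))
    labels = classify_selectivity(profile, fold=10.0, equality_tol_log2=0.5)
    return profile, labels


def _apply_platform_noise(
    expected: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample platform noise applied to a matrix of expected linear signals."""
    n, s = expected.shape
    if config.platform == "ngs":
        if config.depth is None:
            return expected.copy()
        out = np.empty_like(expected)
        for j in range(s):
            p = expected[:, j] / expected[:, j].sum()
            out[:, j] = rng.multinomial(config.depth, p)
        return out
    if config.platform == "hyb":
        noisy = expected + config.background
        if config.hyb_noise_sd > 0:
            noisy = noisy * 2.0 ** rng.normal(0.0, config.hyb_noise_sd, size=(n, s))
        return noisy
    # pcr: quantitation cycles
    eps = np.finfo(float).tiny
    cq = config.cq_intercept - np.log2(np.maximum(expected, eps))
    if config.cq_noise_sd > 0:
        cq = cq + rng.normal(0.0, config.cq_noise_sd, size=(n, s))
    return cq


def simulate_dataset(
    config: SimulationConfig, design: Optional[MixtureDesign] = None
) -> SimulatedDataset:
    """Generate a full reference-sample dataset (pures + mixtures, replicated).

    Mixture samples are built from the ground-truth linear profile via the
    mixing equations (not from resampled pure samples), so the comparison
    of in-silico predictions against "physical" mixtures is exercised
    end to end.  Deterministic given the config seed.
    """
    design = design or make_default_design()
    if tuple(design.component_ids) != _TISSUES:
        raise ValueError(f"simulator components are fixed to {_TISSUES}")
    rng = np.random.default_rng(config.seed)
    profile, labels = simulate_pure_profiles(config, rng)
    manifest = build_manifest(design, config.n_replicates, "full", round_id="sim")

    truth = profile.linear_means.to_numpy()
    expected_cols = []
    for e in manifest.entries:
        if e.kind == "pure":
            expected_cols.append(truth[:, design.component_ids.index(e.target)])
        else:
            expected_cols.append(truth @ design.phi_for(e.target))
    expected = np.column_stack(expected_cols)
    noisy = _apply_platform_noise(expected, config, rng)

    kind = {"ngs": "counts", "hyb": "intensity", "pcr": "cq"}[config.platform]
    table = ExpressionTable(
        pd.DataFrame(noisy, index=profile.mirna_ids, columns=manifest.sample_ids),
        kind,
        manifest,
        provenance={"simulated": True, "seed": config.seed, "platform": config.platform},
    )
    return SimulatedDataset(
        table=table,
        truth_profile=profile,
        truth_labels=labels,
        design=design,
        config=config,
    )
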