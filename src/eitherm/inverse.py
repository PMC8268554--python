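"""Regularized Gauss-Newton difference imaging.

One-step linearized reconstruction with a sensitivity-scaled diagonal prior
(``R_ii = sqrt((J^T J)_ii) * penalty_i``), iterated with reference-model
updates, plus the supporting schemes: tissue-dependent penalties, adaptive
prior regions (1 + 1 + 3 scheme), a positivity constraint on conductivity
changes, measurement-based voltage rescaling and thermal-length Gaussian
smoothing.

Scaling convention
------------------
The reconstruction operates on muscle-normalized absolute conductivity
changes ``x = dsigma / sigma_muscle`` and per-channel *relative* voltage
differences ``y_m = (v_m - v_m(sigma_t)) / |vref_m|``.  Both are
dimensionless, so the hyperparameter ``lambda`` is independent of mesh
scale, injected current and conductivity units, while the solver keeps the
absolute-variable behaviour of standard one-step Gauss-Newton EIT: with a
constant penalty, percentage-scale changes in low-conductivity tissue are
overestimated and high-conductivity tissue underestimated — the failure
mode the tissue-dependent penalty corrects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.linalg as sla

from .forward import ForwardOperator, JacobianMatrix, MeasurementFrame, StimulationPattern
from .mesh import ConductivityField, TetMesh

__all__ = [
    "ReconConfig",
    "ReconResult",
    "regularization_matrix",
    "one_step_gn",
    "tissue_dependent_penalty",
    "iterative_reconstruct",
    "adaptive_prior_reconstruct",
    "rescale_voltages",
    "positivity_constraint",
    "smooth_field",
]

#: Relative floor applied to zero-sensitivity diagonal entries of R.
_R_FLOOR = 1e-12


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings.

    Parameters
    ----------
    hyperparameter:
        Regularization weight lambda (dimensionless, default 0.01).
    penalty_mode:
        ``'none'`` (penalty 1 everywhere), ``'fixed'`` (``penalty_value``
        inside the prior mask) or ``'tissue_dependent'`` (value scaled per
        tissue from the reference conductivity, anchored at muscle).
    penalty_value:
        Base penalty applied inside the prior region (default 0.001, the
        strict setting).  Values < 1 *increase* the permitted change there.
    prior_mask:
        Boolean per-element mask of the prior region, or ``None`` for the
        whole domain.
    n_iterations:
        Gauss-Newton iterations with reference-model update (default 3).
    positivity:
        Zero negative conductivity changes before each iteration.
    smoothing_radius:
        Gaussian smoothing radius in metres used by the adaptive scheme and
        available for output smoothing (default 0.01).
    adaptive_threshold:
        Mask threshold as a fraction of the peak smoothed |change| in the
        adaptive scheme (default 0.25).
    relaxed_penalty / strict_penalty:
        Stage-2 and stage-3 penalties of the adaptive (1 + 1 + 3) scheme.
    """

    hyperparameter: float = 0.01
    penalty_mode: str = "tissue_dependent"
    penalty_value: float = 0.001
    prior_mask: Optional[np.ndarray] = None
    n_iterations: int = 3
    positivity: bool = False
    smoothing_radius: float = 0.01
    adaptive_threshold: float = 0.25
    relaxed_penalty: float = 0.1
    strict_penalty: float = 0.001

    def __post_init__(self) -> None:
        if self.hyperparameter <= 0:
            raise ValueError("hyperparameter must be positive")
        if self.penalty_value <= 0 or self.relaxed_penalty <= 0 or self.strict_penalty <= 0:
            raise ValueError("penalties must be positive")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.penalty_mode not in ("none", "fixed", "tissue_dependent"):
            raise ValueError(f"unknown penalty mode {self.penalty_mode!r}")


@dataclass
class ReconResult:
    """Reconstructed conductivity change with diagnostics.

    ``delta_sigma`` is in S/m; ``delta_sigma_percent`` is relative to the
    non-heated reference conductivity.  ``residuals`` holds (mean, std) of
    |dv| in volts at the start of each iteration performed.
    """

    delta_sigma: np.ndarray
    sigma_final: np.ndarray
    sigma_ref: np.ndarray
    residuals: list
    masks: list
    n_inverse_solves: int
    diverged: bool = False
    sigma_trajectory: list = field(default_factory=list)

    @property
    def delta_sigma_percent(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(self.sigma_ref > 0, self.delta_sigma / self.sigma_ref, 0.0)
        return 100.0 * frac

    def residual_table(self):
        """Per-iteration |dv| statistics as a DataFrame (uV)."""
        import pandas as pd

        return pd.DataFrame(
            [{"iteration": i + 1, "mean_abs_dv_uV": m * 1e6, "std_abs_dv_uV": s * 1e6}
             for i, (m, s) in enumerate(self.residuals)]
        )


def regularization_matrix(J, penalty: np.ndarray) -> np.ndarray:
    """Diagonal of ``R``: column 2-norms of J scaled by the penalty vector.

    Zero-sensitivity columns are floored at ``1e-12 * max(R_ii)`` so the
    inverse stays finite.
    """
    entries = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J)
    penalty = np.asarray(penalty, dtype=float)
    if np.any(penalty <= 0):
        raise ValueError("penalty entries must be strictly positive")
    col = np.sqrt(np.einsum("me,me->e", entries, entries))
    if not np.any(col > 0):
        raise ValueError("all-zero Jacobian")
    r = col * penalty
    r = np.maximum(r, _R_FLOOR * r.max())
    return r


def one_step_gn(J, y: np.ndarray, lam: float, R: np.ndarray) -> np.ndarray:
    """One-step linear Gauss-Newton solution.

    Computes ``x = P J^T (J P J^T + lam^2 I)^{-1} y`` with ``P = R^{-1}``,
    algebraically identical to ``(J^T J + lam^2 R)^{-1} J^T y`` but inverting
    only an (m x m) system.
    """
    entries = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J)
    R = np.asarray(R, dtype=float)
    P = 1.0 / R
    JP = entries * P[None, :]
    inner = JP @ entries.T
    inner[np.diag_indices_from(inner)] += lam ** 2
    try:
        cf = sla.cho_factor(inner, check_finite=False)
        z = sla.cho_solve(cf, y, check_finite=False)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(inner)
        raise np.linalg.LinAlgError(
            f"inner Gauss-Newton system is singular (cond ~ {cond:.3g})"
        ) from exc
    return P * (entries.T @ z)


def tissue_dependent_penalty(
    sigma_ref: ConductivityField | np.ndarray,
    labels: np.ndarray,
    base_penalty: float,
    muscle_sigma: Optional[float] = None,
) -> np.ndarray:
    """Per-element penalty inversely proportional to reference conductivity.

    ``penalty_i = base * sigma_muscle / sigma_ref_i`` clipped to
    ``[base/10, base*100]``: low-conductivity tissues (whose changes a
    constant penalty overestimates) are damped more, high-conductivity
    tissues (underestimated by a constant penalty) are relaxed; muscle keeps
    exactly the base penalty.  Without a muscle reference the median tissue
    conductivity anchors the normalization.
    """
    values = sigma_ref.values if isinstance(sigma_ref, ConductivityField) else np.asarray(sigma_ref)
    if muscle_sigma is None:
        muscle_sigma = float(np.median(values[values > 0])) if np.any(values > 0) else 1.0
    with np.errstate(divide="ignore"):
        p = np.where(values > 0, base_penalty * muscle_sigma / np.maximum(values, 1e-300),
                     base_penalty * 100.0)
    return np.clip(p, base_penalty / 10.0, base_penalty * 100.0)


def _penalty_vector(config: ReconConfig, sigma_ref: np.ndarray, labels: np.ndarray,
                    muscle_sigma: Optional[float], mask: Optional[np.ndarray],
                    base: Optional[float] = None) -> np.ndarray:
    """Penalty per element: 1 outside the prior region, configured inside."""
    n = len(sigma_ref)
    base = config.penalty_value if base is None else base
    if config.penalty_mode == "none":
        inside = np.ones(n)
    elif config.penalty_mode == "fixed":
        inside = np.full(n, base)
    else:
        inside = tissue_dependent_penalty(sigma_ref, labels, base, muscle_sigma)
    if mask is None:
        return inside
    out = np.ones(n)
    out[mask] = inside[mask]
    return out


def _relative_scale(vref: np.ndarray) -> np.ndarray:
    """Per-channel normalization |vref| floored at 1e-3 of the median."""
    mag = np.abs(vref)
    floor = 1e-3 * np.median(mag[mag > 0]) if np.any(mag > 0) else 1.0
    return np.maximum(mag, floor)


def iterative_reconstruct(
    mesh: TetMesh,
    vref: MeasurementFrame,
    v: MeasurementFrame,
    sigma_ref: ConductivityField,
    config: ReconConfig,
    muscle_sigma: Optional[float] = None,
    keep_trajectory: bool = False,
) -> ReconResult:
    """Iterative difference imaging with reference-model updating.

    Per iteration: solve the forward problem at the current conductivity,
    recompute the Jacobian there, reconstruct the remaining fractional change
    with :func:`one_step_gn` and update the conductivity.  Stops early and
    flags divergence if the voltage residual grows for two consecutive
    iterations.
    """
    if v.pattern != vref.pattern:
        raise ValueError("v and vref must share a stimulation pattern")
    if len(sigma_ref) != mesh.n_elements:
        raise ValueError("sigma_ref inconsistent with mesh")
    pattern = v.pattern
    mask = config.prior_mask
    penalty = _penalty_vector(config, sigma_ref.values, mesh.labels, muscle_sigma, mask)
    scale_m = _relative_scale(vref.values)
    if muscle_sigma is None:
        pos = sigma_ref.values[sigma_ref.values > 0]
        muscle_sigma = float(np.median(pos)) if len(pos) else 1.0
    scale_x = float(muscle_sigma)

    sigma_t = sigma_ref.values.copy()
    residuals: list = []
    trajectory: list = []
    diverged = False
    grow = 0
    solves = 0
    for _ in range(config.n_iterations):
        if config.positivity:
            sigma_t = np.maximum(sigma_t, sigma_ref.values)
        op = ForwardOperator(mesh, ConductivityField(sigma_t, sigma_ref.frequency_tag))
        v_t = op.voltages(pattern).values
        dv = v.values - v_t
        residuals.append((float(np.mean(np.abs(dv))), float(np.std(np.abs(dv)))))
        if len(residuals) > 1 and residuals[-1][0] > residuals[-2][0]:
            grow += 1
            if grow >= 2:
                diverged = True
                break
        else:
            grow = 0
        J = op.jacobian(pattern).entries
        Jn = (J * scale_x) / scale_m[:, None]
        y = dv / scale_m
        R = regularization_matrix(Jn, penalty)
        x = one_step_gn(Jn, y, config.hyperparameter, R)
        sigma_t = np.maximum(sigma_t + x * scale_x, 0.0)
        # keep the system connected: elements with a conducting reference
        # may approach but not reach exactly zero
        floor = 1e-6 * sigma_ref.values
        sigma_t = np.where(sigma_ref.values > 0, np.maximum(sigma_t, floor), sigma_t)
        solves += 1
        if keep_trajectory:
            trajectory.append(sigma_t.copy())
    return ReconResult(
        delta_sigma=sigma_t - sigma_ref.values,
        sigma_final=sigma_t,
        sigma_ref=sigma_ref.values.copy(),
        residuals=residuals,
        masks=[mask],
        n_inverse_solves=solves,
        diverged=diverged,
        sigma_trajectory=trajectory,
    )


def adaptive_prior_reconstruct(
    mesh: TetMesh,
    vref: MeasurementFrame,
    v: MeasurementFrame,
    sigma_ref: ConductivityField,
    config: ReconConfig,
    muscle_sigma: Optional[float] = None,
) -> ReconResult:
    """Adaptive prior-region scheme: five (1 + 1 + 3) inverse solves.

    Stage 1 reconstructs once without a prior region and thresholds the
    smoothed |change| to an initial mask; stage 2 reconstructs once with that
    mask at a relaxed penalty and re-thresholds to a refined mask; stage 3
    runs three iterations with the refined mask at the strict penalty.
    """

    def mask_from(result: ReconResult) -> Optional[np.ndarray]:
        frac = np.abs(result.delta_sigma_percent)
        sm = smooth_field(frac, mesh, config.smoothing_radius)
        peak = sm.max()
        if peak <= 0:
            return None
        m = sm > config.adaptive_threshold * peak
        return m if np.any(m) else None

    stage1 = replace(config, penalty_mode="none", prior_mask=None, n_iterations=1)
    r1 = iterative_reconstruct(mesh, vref, v, sigma_ref, stage1, muscle_sigma)
    mask1 = mask_from(r1)
    if mask1 is None:
        warnings.warn("adaptive prior: empty initial mask, using whole domain")

    stage2 = replace(config, penalty_mode="fixed", penalty_value=config.relaxed_penalty,
                     prior_mask=mask1, n_iterations=1)
    r2 = iterative_reconstruct(mesh, vref, v, sigma_ref, stage2, muscle_sigma)
    mask2 = mask_from(r2)
    if mask2 is None:
        warnings.warn("adaptive prior: empty refined mask, using whole domain")

    mode = config.penalty_mode if config.penalty_mode != "none" else "fixed"
    stage3 = replace(config, penalty_mode=mode, penalty_value=config.strict_penalty,
                     prior_mask=mask2, n_iterations=3)
    r3 = iterative_reconstruct(mesh, vref, v, sigma_ref, stage3, muscle_sigma)
    r3.masks = [mask1, mask2]
    r3.n_inverse_solves = r1.n_inverse_solves + r2.n_inverse_solves + r3.n_inverse_solves
    return r3


def rescale_voltages(
    v_meas: MeasurementFrame,
    vref_meas: MeasurementFrame,
    vref_model: MeasurementFrame,
) -> MeasurementFrame:
    """Rescale measured voltages onto the model scale channel-wise.

    ``v_scaled = v_meas * vref_model / vref_meas``; channels whose measured
    reference magnitude is below 1e-3 of the channel median are passed
    through unscaled (the returned frame carries a ``flagged`` attribute).
    """
    if v_meas.pattern != vref_meas.pattern or v_meas.pattern != vref_model.pattern:
        raise ValueError("all frames must share a stimulation pattern")
    mag = np.abs(vref_meas.values)
    floor = 1e-3 * np.median(mag[mag > 0]) if np.any(mag > 0) else np.inf
    ok = mag >= floor
    out = v_meas.values.copy()
    out[ok] = v_meas.values[ok] * vref_model.values[ok] / vref_meas.values[ok]
    frame = MeasurementFrame(out, v_meas.pattern, v_meas.frequency_tag)
    frame.flagged = ~ok  # type: ignore[attr-defined]
    return frame


def positivity_constraint(delta_sigma: np.ndarray) -> np.ndarray:
    """Zero all negative conductivity changes (elementwise max with 0)."""
    return np.maximum(np.asarray(delta_sigma, dtype=float), 0.0)


def smooth_field(field_values: np.ndarray, mesh: TetMesh, radius: float) -> np.ndarray:
    """Volume-weighted Gaussian smoothing over element centroids.

    Weights are ``exp(-d^2 / (2 radius^2)) * V_e`` truncated at 3 radii and
    normalized per element; ``radius = 0`` is the identity.
    """
    field_values = np.asarray(field_values, dtype=float)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return field_values.copy()
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.centroids)
    pairs = tree.sparse_distance_matrix(tree, 3.0 * radius, output_type="coo_matrix")
    w = np.exp(-pairs.data ** 2 / (2.0 * radius ** 2)) * mesh.volumes[pairs.col]
    import scipy.sparse as sp

    W = sp.coo_matrix((w, (pairs.row, pairs.col)), shape=pairs.shape).tocsr()
    norm = np.asarray(W.sum(axis=1)).ravel()
    return (W @ field_values) / norm
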