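"""Scaling of amplitude sets and weighted isomorphous differences.

Light and dark observed amplitudes are brought to a common absolute scale by
fitting a linear scale plus relative isotropic B (k * exp(-B_rel s^2)) against
a reference set, reflections at lower resolution than a configurable cutoff
(default 18 A) excluded.  Per-reflection q-weights then down-weight noisy and
outlying difference amplitudes before the difference Fourier synthesis:

    w_h = 1 / (1 + sigma^2(dF_h)/<sigma^2(dF)> + |dF_h|^2/<|dF|^2>)

The signed weighted difference w * (|F_light| - |F_dark|) is stored in the
amplitude slot, with phases borrowed from the calculated dark model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sf_calc import ReflectionSet, ReflectionError, common_indices

logger = logging.getLogger(__name__)

DEFAULT_LOW_RES_CUTOFF = 18.0  # A; reflections with d above this are excluded


class ScalingError(ValueError):
    """Raised when scaling or weighting cannot proceed."""


@dataclass(frozen=True)
class ScaleResult:
    """Fitted scale between two amplitude sets.

    Attributes
    ----------
    k : linear scale applied to the target amplitudes (dimensionless, > 0).
    b_rel : relative isotropic B in A^2 (positive means the target falls off
        faster with resolution than the reference before correction).
    n_common : reflections entering the fit.
    residual : post-scaling mean absolute relative difference to the reference.
    """

    k: float
    b_rel: float
    n_common: int
    residual: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ScalingError(f"scale factor must be positive, got {self.k}")
        if self.n_common < 2:
            raise ScalingError(f"need at least 2 common reflections, got {self.n_common}")


def scale_to_reference(
    target: ReflectionSet,
    reference: ReflectionSet,
    low_res_cutoff: float = DEFAULT_LOW_RES_CUTOFF,
) -> tuple[ReflectionSet, ScaleResult]:
    """Scale ``target`` amplitudes onto the absolute scale of ``reference``.

    Fits (k, B_rel) minimizing sum (k exp(-B_rel s^2) F_t - F_ref)^2 over the
    common reflections with d <= low_res_cutoff, then applies the fitted
    correction to *all* target reflections (sigmas scaled by the same
    per-reflection factor).
    """
    it, ir = common_indices(target, reference)
    if len(it) == 0:
        raise ScalingError("no common reflections between target and reference")
    d = target.cell.d_spacing(target.hkl[it])
    in_res = d <= low_res_cutoff
    it_fit, ir_fit = it[in_res], ir[in_res]
    if len(it_fit) < 2:
        raise ScalingError(
            f"fewer than 2 common reflections with d <= {low_res_cutoff} A "
            f"({len(it_fit)}); resolution ranges may not overlap"
        )

    f_t = np.abs(target.amplitude[it_fit])
    f_r = np.abs(reference.amplitude[ir_fit])
    s2 = (0.5 / target.cell.d_spacing(target.hkl[it_fit])) ** 2

    # log-linear init: ln(F_ref/F_t) ~ ln k - B_rel s^2
    ok = (f_t > 0) & (f_r > 0)
    if ok.sum() >= 2:
        coeffs = np.polyfit(s2[ok], np.log(f_r[ok] / f_t[ok]), 1)
        x0 = np.array([np.exp(coeffs[1]), -coeffs[0]])
    else:
        x0 = np.array([1.0, 0.0])

    def resid(x):
        k, b = x
        return k * np.exp(-b * s2) * f_t - f_r

    fit = least_squares(resid, x0, method="lm", max_nfev=10000)
    k, b_rel = float(fit.x[0]), float(fit.x[1])

    s2_all = target.s_values() ** 2
    factor = k * np.exp(-b_rel * s2_all)
    scaled = target.copy(
        amplitude=target.amplitude * factor,
        sigma=None if target.sigma is None else target.sigma * factor,
        label=target.label,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(k * np.exp(-b_rel * s2) * f_t - f_r) / np.where(f_r > 0, f_r, np.nan)
    residual = float(np.nanmean(rel))
    result = ScaleResult(k=k, b_rel=b_rel, n_common=int(len(it_fit)), residual=residual)
    logger.info(
        "scaled %r to %r: k=%.6g B_rel=%.4g A^2 over %d reflections (residual %.3g)",
        target.label, reference.label, k, b_rel, result.n_common, residual,
    )
    return scaled, result


def q_weights(delta_f: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Per-reflection q-weights for difference amplitudes.

    w = 1 / (1 + sigma^2/<sigma^2> + dF^2/<dF^2>), means taken over the
    working set.  Large uncertainties and outlying differences are both
    down-weighted; all weights lie in (0, 1).  A term whose mean is zero
    (e.g. noiseless synthetic data with all sigmas 0) drops out.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if delta_f.size == 0:
        raise ScalingError("empty difference set")
    if np.any(sigmas < 0):
        raise ScalingError("negative sigma values")
    mean_var = float(np.mean(sigmas**2))
    mean_df2 = float(np.mean(delta_f**2))
    if mean_var == 0.0 and mean_df2 == 0.0:
        raise ScalingError("all differences and sigmas are zero: weights undefined")
    term_sigma = sigmas**2 / mean_var if mean_var > 0 else 0.0
    term_df = delta_f**2 / mean_df2 if mean_df2 > 0 else 0.0
    return 1.0 / (1.0 + term_sigma + term_df)


def weighted_difference(
    light: ReflectionSet,
    dark: ReflectionSet,
    dark_phases: ReflectionSet,
    apply_weights: bool = True,
) -> ReflectionSet:
    """Signed, weighted difference structure factors with dark-model phases.

    Per common (h,k,l): amplitude = w * (|F_light| - |F_dark|), stored signed;
    sigma(dF) = sqrt(sigma_light^2 + sigma_dark^2); phase copied from the
    calculated dark set.  Reflections missing from any input are dropped (the
    count is logged).  Assumes light and dark are already on a common scale.
    """
    il, id_ = common_indices(light, dark)
    if len(il) == 0:
        raise ScalingError("light and dark share no reflections")
    sub_light = light.take(il)
    sub_dark = dark.take(id_)
    ic, ip = common_indices(sub_light, dark_phases)
    if len(ic) == 0:
        raise ScalingError("dark-phase set shares no reflections with the difference set")
    n_dropped = len(light) + len(dark) - len(il) - len(id_) + (len(il) - len(ic))
    if n_dropped:
        logger.info("dropped %d reflections absent from one of the inputs", n_dropped)

    sub_light = sub_light.take(ic)
    sub_dark = sub_dark.take(ic)
    if dark_phases.phase is None:
        raise ScalingError("dark phase set carries no phases")
    phases = dark_phases.phase[ip]

    diff = np.abs(sub_light.amplitude) - np.abs(sub_dark.amplitude)
    sig_l = sub_light.sigma if sub_light.sigma is not None else np.zeros(len(diff))
    sig_d = sub_dark.sigma if sub_dark.sigma is not None else np.zeros(len(diff))
    sigma = np.sqrt(sig_l**2 + sig_d**2)
    if apply_weights and (np.any(diff != 0) or np.any(sigma != 0)):
        w = q_weights(diff, sigma)
    else:
        if apply_weights:
            logger.info("all differences and sigmas are zero; weights fixed at 1")
        w = np.ones_like(diff)
    return ReflectionSet(
        hkl=sub_light.hkl,
        amplitude=w * diff,
        cell=light.cell,
        sigma=sigma,
        phase=phases,
        weight=w,
        label="dF_obs",
    )
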