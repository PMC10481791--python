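"""Anhysteretic B-H constitutive models for soft magnetic core materials.

Two single-valued magnetization models are supported, both written for the
permeability as a function of the field-intensity magnitude ``H = |H|``:

* inverse-tangent ("arctan") model::

      mu0 * mu_r(H) = a1 * atan(a2 * H) / H + mu0

  with ``a1`` in tesla and ``a2`` in m/A; and

* Froelich model::

      mu0 * mu_r(H) = 1 / (a1 + a2 * H) + mu0

  with ``a1`` in m/H and ``a2`` in 1/T.

The additive ``mu0`` term gives both models the physically correct vacuum
floor ``mu_r -> 1`` deep in saturation; it matters for accurate numerics at
TMS-level flux densities.  Hysteresis, coercivity and loss models are out of
scope: the curves here are anhysteretic fits to the outermost loop loci of a
datasheet (see :func:`fit_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

MU0: float = 4e-7 * np.pi
"""Vacuum permeability, H/m."""

# Below this field magnitude (A/m) the arctan model is evaluated through its
# analytic H -> 0 limit to avoid 0/0.
_H_SMALL = 1e-6

ARCTAN = "arctan"
FROELICH = "froelich"


@dataclass(frozen=True)
class AnhystereticCurve:
    """Single-valued anhysteretic B-H curve.

    Parameters
    ----------
    kind:
        ``"arctan"`` or ``"froelich"``.
    a1, a2:
        Positive model coefficients.  Units depend on ``kind`` (see module
        docstring).
    """

    kind: str
    a1: float
    a2: float

    def __post_init__(self) -> None:
        if self.kind not in (ARCTAN, FROELICH):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not (self.a1 > 0 and self.a2 > 0):
            raise ValueError("curve coefficients a1, a2 must be positive")

    # Convenience method forms of the module-level operations -------------
    def relative_permeability(self, H_mag):
        return relative_permeability(self, H_mag)

    def flux_density(self, H_mag):
        return flux_density(self, H_mag)

    @property
    def initial_permeability(self) -> float:
        return initial_permeability(self)

    @property
    def saturation_flux_excess(self) -> float:
        return saturation_flux_excess(self)


def _check_H(H_mag):
    H = np.asarray(H_mag, dtype=float)
    if np.any(H < 0):
        raise ValueError("field magnitude H must be non-negative")
    return H


def relative_permeability(curve: AnhystereticCurve, H_mag):
    """Relative permeability mu_r(|H|), dimensionless.

    Accepts scalars or arrays.  The arctan model's removable singularity at
    H = 0 is evaluated through the analytic limit ``(a1*a2 + mu0)/mu0``.
    """
    H = _check_H(H_mag)
    scalar = H.ndim == 0
    H = np.atleast_1d(H)
    if curve.kind == ARCTAN:
        out = np.empty_like(H)
        small = H < _H_SMALL
        out[small] = curve.a1 * curve.a2 + MU0
        Hb = H[~small]
        out[~small] = curve.a1 * np.arctan(curve.a2 * Hb) / Hb + MU0
    else:
        out = 1.0 / (curve.a1 + curve.a2 * H) + MU0
    out /= MU0
    return out[0] if scalar else out


def flux_density(curve: AnhystereticCurve, H_mag):
    """Flux density magnitude B = mu0 * mu_r(|H|) * |H|, tesla."""
    H = _check_H(H_mag)
    return MU0 * relative_permeability(curve, H) * H


def initial_permeability(curve: AnhystereticCurve) -> float:
    """Small-signal relative permeability mu_r0 = mu_r(H -> 0)."""
    if curve.kind == ARCTAN:
        return (curve.a1 * curve.a2 + MU0) / MU0
    return (1.0 / curve.a1 + MU0) / MU0


def saturation_flux_excess(curve: AnhystereticCurve) -> float:
    """Large-H limit of B - mu0*H, tesla.

    This is the ferromagnetic contribution ceiling: ``a1*pi/2`` for the
    arctan model and ``1/a2`` for the Froelich model.
    """
    if curve.kind == ARCTAN:
        return curve.a1 * np.pi / 2.0
    return 1.0 / curve.a2


def permeability_rate(curve: AnhystereticCurve, H_mag):
    """Derivative d(mu0*mu_r)/d|H| (henry per ampere), analytic."""
    H = _check_H(H_mag)
    scalar = np.ndim(H) == 0
    H = np.atleast_1d(np.asarray(H, dtype=float))
    if curve.kind == ARCTAN:
        out = np.zeros_like(H)
        small = H < _H_SMALL
        Hb = H[~small]
        x = curve.a2 * Hb
        out[~small] = curve.a1 * (x / (1.0 + x * x) - np.arctan(x)) / Hb**2
        # Taylor: -(2/3) a1 a2^3 H near the origin
        out[small] = -(2.0 / 3.0) * curve.a1 * curve.a2**3 * H[small]
    else:
        out = -curve.a2 / (curve.a1 + curve.a2 * H) ** 2
    return out[0] if scalar else out


def max_permeability_rate(curve: AnhystereticCurve) -> float:
    """Maximum of |d(mu0*mu_r)/d|H|| over H >= 0, henry per ampere.

    The Froelich model attains its maximum ``a2/a1**2`` at H = 0 (closed
    form).  The arctan maximum is interior; it is located on a log-spaced
    grid over H in [1e-2, 1e7] A/m and refined with bounded scalar
    minimization.
    """
    if curve.kind == FROELICH:
        return curve.a2 / curve.a1**2
    H = np.logspace(-2, 7, 2000)
    r = np.abs(permeability_rate(curve, H))
    i = int(np.argmax(r))
    lo = H[max(i - 1, 0)]
    hi = H[min(i + 1, H.size - 1)]
    res = optimize.minimize_scalar(
        lambda h: -abs(permeability_rate(curve, h)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6 * hi},
    )
    return float(-res.fun)


def preset_material(material_id: int) -> AnhystereticCurve:
    """One of the three study materials.

    1. generic high-saturation material, arctan model
       (a1 = 5/pi T, a2 = 5e-4 m/A);
    2. 2-mil M3 grain-oriented silicon steel at 2 kHz, Froelich fit
       (a1 = 40 m/H, a2 = 0.50 1/T);
    3. METGLAS 2605-SA1 amorphous foil, Froelich fit
       (a1 = 80 m/H, a2 = 0.82 1/T).
    """
    presets = {
        1: AnhystereticCurve(ARCTAN, 5.0 / np.pi, 5e-4),
        2: AnhystereticCurve(FROELICH, 40.0, 0.50),
        3: AnhystereticCurve(FROELICH, 80.0, 0.82),
    }
    try:
        return presets[int(material_id)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"unknown preset material id {material_id!r}") from None


class FitError(RuntimeError):
    """Raised when a B-H locus fit fails to converge; carries residuals."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def fit_curve(loci, kind: str) -> AnhystereticCurve:
    """Least-squares fit of (a1, a2) to datasheet locus points.

    Parameters
    ----------
    loci:
        Sequence of ``(H_max, B_max)`` pairs (A/m, T), e.g. the tips of
        symmetric hysteresis cycles from a datasheet.  A ``(0, 0)`` origin
        point is implied and may be included; it carries no information for
        the relative-residual objective used here.
    kind:
        Model to fit, ``"arctan"`` or ``"froelich"``.

    Notes
    -----
    The objective is the relative B-residual ``(B_model - B)/B`` over the
    positive-H loci, with positivity enforced by optimizing log-parameters;
    locus fields typically span several decades so absolute residuals would
    be dominated by the saturated points.
    """
    pts = np.asarray(loci, dtype=float).reshape(-1, 2)
    pts = pts[pts[:, 0] > 0]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 locus points with positive H")
    H, B = pts[:, 0], pts[:, 1]
    if np.any(B <= 0):
        raise ValueError("locus flux densities must be positive at H > 0")

    ferro = B - MU0 * H  # ferromagnetic part of the flux density
    if np.any(ferro <= 0):
        raise ValueError("locus points lie below the vacuum line B = mu0*H")

    if kind == FROELICH:
        # B - mu0 H = H/(a1 + a2 H)  =>  H/(B - mu0 H) = a1 + a2 H: linear LSQ
        y = H / ferro
        A = np.column_stack([np.ones_like(H), H])
        (a1_0, a2_0), *_ = np.linalg.lstsq(A, y, rcond=None)
        a1_0 = max(a1_0, 1e-12)
        a2_0 = max(a2_0, 1e-12)
    elif kind == ARCTAN:
        # a1 from the most saturated point, a2 from the least saturated one
        a1_0 = max(ferro.max() * 2.0 / np.pi, 1e-12)
        x = np.clip(ferro[np.argmin(H)] / a1_0, 1e-9, 1 - 1e-9)
        a2_0 = np.tan(np.pi / 2 * x) / H[np.argmin(H)]
    else:
        raise ValueError(f"unknown curve kind {kind!r}")

    def residual(logp):
        c = AnhystereticCurve(kind, np.exp(logp[0]), np.exp(logp[1]))
        return flux_density(c, H) / B - 1.0

    res = optimize.least_squares(residual, np.log([a1_0, a2_0]), method="lm")
    if not res.success:
        raise FitError(
            f"B-H curve fit did not converge: {res.message}", residuals=res.fun
        )
    a1, a2 = np.exp(res.x)
    return AnhystereticCurve(kind, float(a1), float(a2))
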