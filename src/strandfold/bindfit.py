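"""Equilibrium binding and mass-photometry estimation.

One-site binding fits with Hill slope (EMSA percent-bound titrations), simple
one-site fluorescence-polarization fits (hyperbolic, hill = 1), an optional
ligand-depletion (quadratic) variant for tight binders, mass-photometry
contrast calibration, Gaussian-mixture fitting of mass histograms, and
assignment of peak masses to CAF-1 / PCNA-trimer stoichiometries.

The binding model is

    response(c) = baseline + amplitude * c**h / (Kd**h + c**h)

fit by nonlinear least squares from multiple starting points (Kd at the
concentration nearest half-maximal response and at geometric quartiles of the
concentration range; h in {0.5, 1, 2} when free); the lowest residual sum of
squares wins. The fit is covariant under joint rescaling of concentrations
and Kd, so any concentration unit can be used as long as it is consistent.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats

from strandfold.core import BindingFit, CompositionModel, MassPeakSet, TitrationCurve, hill_response

MIN_POINTS = 5


def _start_kds(curve: TitrationCurve) -> list[float]:
    pos = curve.concentration[curve.concentration > 0]
    if pos.size == 0:
        raise ValueError("curve needs positive concentrations")
    resp = curve.response
    half = (resp.min() + resp.max()) / 2.0
    nearest = float(curve.concentration[np.argmin(np.abs(resp - half))])
    lo, hi = float(pos.min()), float(pos.max())
    quartiles = [float(np.exp(q)) for q in np.linspace(np.log(lo), np.log(hi), 5)[1:-1]]
    starts = [k for k in [nearest, *quartiles] if k > 0]
    return sorted(set(starts))


def _fit_curve(
    curve: TitrationCurve, hill_fixed: float | None, hill_starts: tuple[float, ...]
) -> BindingFit:
    if len(curve) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} titration points")
    c, y = curve.concentration, curve.response
    amp0 = float(y.max() - y.min()) or 1.0
    base0 = float(y.min())
    best: tuple[float, np.ndarray] | None = None

    if hill_fixed is not None:

        def model(cc, kd, amplitude, baseline):
            return hill_response(cc, kd, hill_fixed, amplitude, baseline)

        n_extra = 0
        bounds = ([1e-30, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    else:

        def model(cc, kd, hill, amplitude, baseline):
            return hill_response(cc, kd, hill, amplitude, baseline)

        n_extra = 1
        bounds = ([1e-30, 1e-3, -np.inf, -np.inf], [np.inf, 20.0, np.inf, np.inf])

    for kd0, h0 in itertools.product(_start_kds(curve), hill_starts):
        p0 = [kd0, amp0, base0] if hill_fixed is not None else [kd0, h0, amp0, base0]
        try:
            popt, _ = optimize.curve_fit(model, c, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(c, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)

    if best is None:
        return BindingFit(
            kd=float("nan"), hill=hill_fixed or float("nan"), amplitude=float("nan"),
            baseline=float("nan"), rss=float("inf"), converged=False,
        )
    rss, popt = best
    if hill_fixed is not None:
        kd, amplitude, baseline = popt
        hill = hill_fixed
    else:
        kd, hill, amplitude, baseline = popt
    # Kd is unidentifiable when the response never rises above noise
    converged = bool(np.isfinite(kd) and abs(amplitude) > 1e-9 * max(1.0, abs(baseline)))
    return BindingFit(
        kd=float(kd), hill=float(hill), amplitude=float(amplitude),
        baseline=float(baseline), rss=rss, converged=converged,
    )


def fit_one_site_hill(curve: TitrationCurve, constrain_hill: float | None = None) -> BindingFit:
    """Fit the one-site-with-Hill-slope model to a titration.

    ``constrain_hill`` fixes the Hill coefficient (e.g. 1 for short duplexes
    where cooperativity is not expected); otherwise h is free and started
    from {0.5, 1, 2}.
    """
    if constrain_hill is not None and constrain_hill <= 0:
        raise ValueError("constrained hill must be positive")
    return _fit_curve(curve, hill_fixed=constrain_hill, hill_starts=(0.5, 1.0, 2.0))


def fit_fp_one_site(curve: TitrationCurve, probe_concentration: float | None = None) -> BindingFit:
    """Fit a fluorescence-polarization titration with a simple one-site model.

    The hyperbolic (hill = 1) form is the default, matching standard FP
    analysis; baseline is the free-probe polarization and amplitude the
    bound-minus-free polarization change. When the fitted Kd is comparable to
    or below the labeled-probe concentration, the free-ligand approximation
    breaks down; pass ``probe_concentration`` to use the ligand-depletion
    (quadratic) binding isotherm instead.
    """
    if probe_concentration is None:
        return _fit_curve(curve, hill_fixed=1.0, hill_starts=(1.0,))
    if probe_concentration <= 0:
        raise ValueError("probe concentration must be positive")
    if len(curve) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} titration points")
    c, y = curve.concentration, curve.response
    P = probe_concentration

    def depletion(cc, kd, amplitude, baseline):
        s = cc + P + kd
        bound = (s - np.sqrt(np.maximum(s * s - 4.0 * cc * P, 0.0))) / (2.0 * P)
        return baseline + amplitude * bound

    best = None
    for kd0 in _start_kds(curve):
        try:
            popt, _ = optimize.curve_fit(
                depletion, c, y,
                p0=[kd0, float(y.max() - y.min()) or 1.0, float(y.min())],
                bounds=([1e-30, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((depletion(c, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return BindingFit(float("nan"), 1.0, float("nan"), float("nan"), float("inf"), False)
    rss, (kd, amplitude, baseline) = best[0], best[1]
    return BindingFit(float(kd), 1.0, float(amplitude), float(baseline), rss, True)


# ---------------------------------------------------------------------------
# mass photometry


def mp_calibrate(contrasts: np.ndarray, standard_masses: np.ndarray) -> tuple[float, float, float]:
    """Linear contrast-to-mass calibration against protein standards.

    Returns (slope, intercept, r_squared) of the least-squares line
    mass_kDa = slope * contrast + intercept. Two standards give exact
    interpolation; typical standard mixtures span ~70-800 kDa.
    """
    x = np.asarray(contrasts, dtype=float)
    m = np.asarray(standard_masses, dtype=float)
    if x.shape != m.shape or x.size < 2:
        raise ValueError("need >= 2 matched (contrast, mass) standards")
    if np.unique(x).size < 2:
        raise ValueError("degenerate contrasts")
    res = stats.linregress(x, m)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_mass_peaks(masses: np.ndarray, k: int, seed: int = 0) -> MassPeakSet:
    """Fit a k-component Gaussian mixture (shared sigma) to landing-event masses.

    Means are returned sorted ascending; the fit is deterministic for a fixed
    seed. ``k`` is chosen by the caller (the number of visible histogram
    peaks). Requires at least 10 events per component.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(masses, dtype=float).reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} events for k={k}")
    gm = GaussianMixture(
        n_components=k, covariance_type="tied", n_init=5, random_state=seed
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_[order]
    sigma = float(np.sqrt(gm.covariances_.ravel()[0]))
    return MassPeakSet(
        means_kda=tuple(float(m) for m in means),
        weights=tuple(float(w) for w in weights / weights.sum()),
        sigma_kda=sigma,
    )


def assign_composition(
    peak_mass: float, model: CompositionModel | None = None, tolerance: float = 50.0
) -> tuple[int, int] | None:
    """Assign a fitted peak mass to an (n_CAF-1, m_PCNA-trimer) stoichiometry.

    Exhaustive search over 0 <= a <= max_caf1, 0 <= b <= max_pcna3 with
    (a, b) != (0, 0), minimizing |peak - a*M_caf1 - b*M_pcna3|; ties go to the
    smaller total subunit count. Returns None when the best residual exceeds
    ``tolerance`` (generous by default: instrument-fitted masses of large
    assemblies deviate from naive subunit sums).
    """
    if model is None:
        model = CompositionModel()
    best: tuple[float, int, int, int] | None = None
    for a in range(model.max_caf1 + 1):
        for b in range(model.max_pcna3 + 1):
            if a == 0 and b == 0:
                continue
            resid = abs(peak_mass - a * model.m_caf1 - b * model.m_pcna3)
            key = (resid, a + b, a, b)
            if best is None or key < (best[0], best[1], best[2], best[3]):
                best = (resid, a + b, a, b)
    assert best is not None
    if best[0] > tolerance:
        return None
    return best[2], best[3]
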