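"""Mixed-effects 4PL calibration of enzymatic inhibition assays.

Background-corrected microplate absorbances are fitted with the 4-parameter
logistic Absorbance = A + (B - A) / (1 + exp((x_mid - x) / scal)): A is the
fully active (uninhibited) asymptote, B the fully inhibited one, x_mid the
midpoint and scal the shape. The shared ``scal`` is profiled over a grid and
chosen by AIC; extracts contribute random deviates on x_mid, estimated by
Laplace-approximate maximum likelihood. An ouabain calibration curve on the
same plate converts extract midpoints into ouabain equivalents per mg dry
tissue.

Sample ``x`` is the log10 dilution factor (0, 0.699, 1.699, 2.699 for 1:1,
1:5, 1:50, 1:500); calibration ``x`` is log10 molar concentration. The mixed
fit works internally on -x (log10 relative concentration) so one positive
``scal`` orients both curve families identically; reported midpoints are on
the input dilution scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import four_pl

OUABAIN_MOLAR_MASS = 584.65  # g/mol


class ConvergenceError(RuntimeError):
    """No scal grid point produced a converged fit."""


#: 21 log-spaced shape candidates; includes 0.5 exactly (0.05 * 10^(k/10)).
DEFAULT_SCAL_GRID = tuple(np.round(0.05 * 10 ** (np.arange(21) / 10.0), 10))


def correct_background(plate: pd.DataFrame) -> pd.DataFrame:
    """Subtract each well's paired background absorbance.

    Requires ``absorbance`` and ``background`` columns; returns a copy with a
    ``corrected`` column. Negative corrected values are retained (flagged in
    ``negative_corrected``), not clamped.
    """
    if "absorbance" not in plate or "background" not in plate:
        raise ValueError("plate needs 'absorbance' and 'background' columns")
    if plate["background"].isna().any():
        raise ValueError("every reaction well needs a paired background well")
    out = plate.copy()
    out["corrected"] = out["absorbance"] - out["background"]
    out["negative_corrected"] = out["corrected"] < 0
    return out


# --------------------------------------------------------------------------
# mixed 4PL fit
# --------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Shared-asymptote 4PL mixed fit across extracts."""

    A: float
    B: float
    scal: float
    x_mid_fixed: float  # dilution-scale fixed midpoint
    x_mid: pd.Series  # per-extract midpoints (fixed + predicted deviate)
    sigma_b: float  # SD of the extract random deviates
    sigma_resid: float
    aic: float
    aic_by_scal: pd.Series
    method: str = "laplace_ml"
    converged: bool = True
    notes: str = ""


def _profile_deviates(A, B, m0, scal, sb2, se2, x_cat, y_cat, gidx, n_groups, b0):
    """Conditional modes of the midpoint deviates, one damped Gauss-Newton
    pass over all extracts simultaneously."""
    from scipy.special import expit

    b = b0.copy()

    def penalized(bv):
        r = y_cat - four_pl(x_cat, A, B, m0 + bv[gidx], scal)
        return (
            0.5 * np.bincount(gidx, r * r, n_groups) / se2 + 0.5 * bv * bv / sb2
        )

    obj = penalized(b)
    for _ in range(50):
        m = m0 + b[gidx]
        s = expit((x_cat - m) / scal)
        f = A + (B - A) * s
        r = y_cat - f
        fp = -(B - A) * s * (1 - s) / scal  # df/db
        grad = -np.bincount(gidx, r * fp, n_groups) / se2 + b / sb2
        curv = np.bincount(gidx, fp * fp, n_groups) / se2 + 1.0 / sb2
        step = grad / curv
        # backtracking: halve per-extract steps that increase the objective
        for _ in range(20):
            cand = b - step
            obj_cand = penalized(cand)
            worse = obj_cand > obj + 1e-14
            if not np.any(worse):
                break
            step = np.where(worse, step * 0.5, step)
        b = b - step
        new_obj = penalized(b)
        if np.max(np.abs(step)) < 1e-12 or np.max(obj - new_obj) < 1e-15:
            obj = new_obj
            break
        obj = new_obj
    m = m0 + b[gidx]
    s = expit((x_cat - m) / scal)
    fp = -(B - A) * s * (1 - s) / scal
    curv = np.bincount(gidx, fp * fp, n_groups) / se2 + 1.0 / sb2
    return b, obj, curv


def _neg_marg_ll(theta, scal, x_cat, y_cat, gidx, n_groups, b0):
    """Laplace-approximate negative marginal log-likelihood.

    theta = (A, B, m0, log sigma_b, log sigma_e); the random deviate b_i on
    the midpoint is integrated out by a Gauss-Newton Laplace approximation.
    """
    A, B, m0, log_sb, log_se = theta
    sb2, se2 = np.exp(2 * log_sb), np.exp(2 * log_se)
    b, obj, curv = _profile_deviates(
        A, B, m0, scal, sb2, se2, x_cat, y_cat, gidx, n_groups, b0
    )
    counts = np.bincount(gidx, minlength=n_groups)
    nll = (
        np.sum(obj)
        + 0.5 * counts.sum() * np.log(2 * np.pi * se2)
        + 0.5 * n_groups * np.log(sb2)
        + 0.5 * np.sum(np.log(curv))
    )
    return nll


def _joint_ls(scal, groups, x_all, y_all):
    """Joint least squares over (A, B, m_1..m_G) at fixed scal."""
    n_groups = len(groups)

    def resid(params):
        A, B = params[0], params[1]
        out = []
        for gi, (x, y) in enumerate(groups):
            out.append(y - four_pl(x, A, B, params[2 + gi], scal))
        return np.concatenate(out)

    A0, B0 = float(np.max(y_all)), float(np.min(y_all))
    m0 = float(np.median(x_all))
    start = np.concatenate([[A0, B0], np.full(n_groups, m0)])
    sol = optimize.least_squares(resid, start, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return sol


def fit_4pl_mixed(
    plate: pd.DataFrame,
    scal_grid: Optional[Sequence[float]] = None,
    random_effect: str = "x_mid",
) -> DoseResponseFit:
    """Fit the mixed-effects 4PL to sample wells, profiling scal by AIC.

    For each candidate ``scal``, shared A and B, a fixed midpoint, and a
    per-extract Gaussian deviate on the midpoint are estimated by maximum
    likelihood (Laplace approximation, seeded by a joint least-squares fit).
    The returned fit minimizes AIC over the grid; per-extract ``x_mid`` is
    the fixed midpoint plus the predicted deviate, reported on the input
    dilution scale. A single extract falls back to a fixed-effects fit.
    """
    if random_effect != "x_mid":
        raise NotImplementedError("random effects are supported on x_mid only")
    scal_grid = tuple(scal_grid) if scal_grid is not None else DEFAULT_SCAL_GRID
    if not scal_grid:
        raise ValueError("scal grid must be non-empty")
    wells = plate[plate["role"] == "sample"] if "role" in plate else plate
    if not len(wells):
        raise ValueError("no sample wells on the plate")
    wells = correct_background(wells)

    groups, names = [], []
    for extract, sub in wells.groupby("extract_id", sort=True):
        if sub["x"].nunique() < 4:
            raise ValueError(f"extract {extract!r} has fewer than 4 dilution levels")
        # internal concentration scale: higher value = more concentrated
        groups.append((-sub["x"].to_numpy(float), sub["corrected"].to_numpy(float)))
        names.append(extract)
    x_all = np.concatenate([g[0] for g in groups])
    y_all = np.concatenate([g[1] for g in groups])
    n_obs = len(y_all)
    single = len(groups) == 1

    best = None
    aics = {}
    for scal in scal_grid:
        try:
            ls = _joint_ls(scal, groups, x_all, y_all)
        except Exception:
            continue
        A, B = ls.x[0], ls.x[1]
        m = ls.x[2:]
        sse = float(2 * ls.cost)
        se2 = max(sse / n_obs, 1e-16)
        m0 = float(np.mean(m))
        b = m - m0
        sb2 = max(float(np.mean(b**2)), 1e-16)

        if single or se2 < 1e-12:
            # noiseless or degenerate: the LS solution is the ML solution
            # (no shrinkage as sigma_e -> 0); Gaussian ll with plugin se2
            nll = 0.5 * n_obs * (np.log(2 * np.pi * se2) + sse / (n_obs * se2))
            k = 4 if single else 5  # A, B, m0, sigma_e (+ sigma_b)
            aic = 2 * nll + 2 * k
            cand = dict(
                A=A, B=B, m0=m0, b=b, sb=np.sqrt(sb2) if not single else float("nan"),
                se=np.sqrt(se2), aic=aic, scal=scal, method="least_squares",
            )
        else:
            gidx = np.concatenate(
                [np.full(len(g[0]), gi) for gi, g in enumerate(groups)]
            )
            theta0 = np.array([A, B, m0, 0.5 * np.log(sb2), 0.5 * np.log(se2)])
            res = optimize.minimize(
                _neg_marg_ll,
                theta0,
                args=(scal, x_all, y_all, gidx, len(groups), b.copy()),
                method="Nelder-Mead",
                options={"maxiter": 3000, "xatol": 1e-9, "fatol": 1e-10},
            )
            if not np.isfinite(res.fun):
                continue
            A_, B_, m0_, lsb, lse = res.x
            sb2_, se2_ = np.exp(2 * lsb), np.exp(2 * lse)
            b_hat, _, _ = _profile_deviates(
                A_, B_, m0_, scal, sb2_, se2_, x_all, y_all, gidx, len(groups),
                b.copy(),
            )
            k = 5  # A, B, m0, sigma_b, sigma_e
            aic = 2 * res.fun + 2 * k
            cand = dict(
                A=A_, B=B_, m0=m0_, b=b_hat, sb=np.sqrt(sb2_),
                se=np.sqrt(se2_), aic=aic, scal=scal, method="laplace_ml",
            )
        aics[scal] = cand["aic"]
        if best is None or cand["aic"] < best["aic"]:
            best = cand
    if best is None:
        raise ConvergenceError("no scal grid point produced a converged fit")

    # back to the dilution scale: x_mid(dilution) = -m(concentration)
    x_mid = pd.Series(
        {name: float(-(best["m0"] + bi)) for name, bi in zip(names, best["b"])},
        name="x_mid",
    )
    return DoseResponseFit(
        A=float(best["A"]),
        B=float(best["B"]),
        scal=float(best["scal"]),
        x_mid_fixed=float(-best["m0"]),
        x_mid=x_mid,
        sigma_b=float(best["sb"]),
        sigma_resid=float(best["se"]),
        aic=float(best["aic"]),
        aic_by_scal=pd.Series(aics, name="aic"),
        method=best["method"],
        notes="single extract: fixed-effects fallback" if single else "",
    )


# --------------------------------------------------------------------------
# ouabain calibration
# --------------------------------------------------------------------------


@dataclass
class CalibrationFit:
    """Single-series 4PL fit of the ouabain standard curve."""

    A: float
    B: float
    x_mid: float  # log10 molar concentration at 50% inhibition
    scal: float
    ic50: float  # molar

    def predict(self, x):
        return four_pl(np.asarray(x, float), self.A, self.B, self.x_mid, self.scal)


def calibrate_ouabain(calibration_wells: pd.DataFrame) -> CalibrationFit:
    """Fit the ouabain calibration series (log10 molar x).

    Exposes the concentration giving 50% inhibition (IC50 = 10^x_mid M).
    Raises :class:`ConvergenceError` for flat or otherwise degenerate data.
    """
    wells = (
        calibration_wells[calibration_wells["role"] == "calibration"]
        if "role" in calibration_wells
        else calibration_wells
    )
    wells = correct_background(wells)
    x = wells["x"].to_numpy(float)
    y = wells["corrected"].to_numpy(float)
    if len(np.unique(x)) < 4:
        raise ValueError("calibration needs at least 4 concentrations")
    if np.ptp(y) < 1e-12:
        raise ConvergenceError("calibration absorbances are flat: no signal")

    def resid(params):
        A, B, m, s = params
        return y - four_pl(x, A, B, m, s)

    start = np.array([float(y.max()), float(y.min()), float(np.median(x)), 0.5])
    sol = optimize.least_squares(resid, start, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    A, B, m, s = sol.x
    if not sol.success or not np.isfinite(sol.x).all():
        raise ConvergenceError("calibration fit did not converge")
    if A < B:  # reparameterize to the inhibition orientation A > B
        A, B, s = B, A, -s
    return CalibrationFit(A=float(A), B=float(B), x_mid=float(m), scal=float(s),
                          ic50=float(10.0**m))


# --------------------------------------------------------------------------
# ouabain equivalents
# --------------------------------------------------------------------------


@dataclass
class PrepConfig:
    """Extract preparation chain from dry tissue to the 1:1 assay well.

    Defaults follow a 10 mg dry tissue per mL extraction, drying of a 100 uL
    aliquot, reconstitution in 200 uL, and a 1:5 in-well dilution (20 uL
    extract in a 100 uL reaction).
    """

    tissue_mg_per_ml: float = 10.0
    aliquot_ml: float = 0.1
    reconstitution_ml: float = 0.2
    in_well_dilution: float = 5.0

    def stock_factor(self) -> float:
        """Concentration factor from the 1:1 well back to the original extract."""
        return (self.reconstitution_ml / self.aliquot_ml) * self.in_well_dilution


@dataclass
class EquivalentsResult:
    """Extract potency in ouabain equivalents."""

    molar_well: pd.Series  # equivalents in the undiluted (1:1) well, M
    molar_stock: pd.Series  # equivalents of the original extract, M
    ug_per_mg: pd.Series  # ouabain ug per mg dry tissue
    extrapolated: pd.Series  # x_mid outside the tested dilution range
    constants: dict = field(default_factory=dict)


def ouabain_equivalents(
    sample_fit: DoseResponseFit,
    calib_fit: CalibrationFit,
    prep: Optional[PrepConfig] = None,
    tested_x_range: tuple = (0.0, np.log10(500.0)),
) -> EquivalentsResult:
    """Convert extract midpoints into ouabain equivalents per mg dry tissue.

    At an extract's midpoint the well produces 50% inhibition, i.e. the well
    content equals the ouabain IC50; the undiluted well is therefore
    ``IC50_ouabain * 10^x_mid`` molar, scaled back through the preparation
    chain and the ouabain molar mass (584.65 g/mol) to ug per mg dry tissue.
    Midpoints outside the tested dilution range are flagged as extrapolated.
    """
    prep = prep or PrepConfig()
    if prep.tissue_mg_per_ml <= 0:
        raise ValueError("tissue concentration must be positive")
    factor = prep.stock_factor()
    molar_well = (calib_fit.ic50 * 10.0**sample_fit.x_mid).rename("molar_well")
    molar_stock = (molar_well * factor).rename("molar_stock")
    # M * g/mol = g/L = 1000 ug/mL; divide by mg tissue per mL
    ug_per_mg = (
        molar_stock * OUABAIN_MOLAR_MASS * 1000.0 / prep.tissue_mg_per_ml
    ).rename("ug_per_mg")
    lo, hi = tested_x_range
    extrapolated = ~sample_fit.x_mid.between(lo, hi)
    return EquivalentsResult(
        molar_well=molar_well,
        molar_stock=molar_stock,
        ug_per_mg=ug_per_mg,
        extrapolated=extrapolated.rename("extrapolated"),
        constants={
            "ouabain_ic50_M": calib_fit.ic50,
            "ouabain_molar_mass_g_per_mol": OUABAIN_MOLAR_MASS,
            "stock_factor": factor,
            "tissue_mg_per_ml": prep.tissue_mg_per_ml,
        },
    )
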