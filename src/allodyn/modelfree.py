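"""Lipari-Szabo model-free analysis of backbone 15N relaxation.

The amide 15N R1, R2 and heteronuclear 1H->15N NOE report on reorientational
motion of each N-H bond vector through the spectral density J(omega) sampled
at {0, wN, wH-wN, wH, wH+wN}.  The model-free spectral density separates
overall tumbling (global correlation time tau_m) from fast internal motion
described by a generalized order parameter S^2 (1 = rigid, 0 = isotropic
disorder) and an effective internal correlation time tau_e; slow exchange
broadening enters R2 as an additive Rex term.  In the extended (two
timescale) form a fast-motion amplitude Sf^2 factors out, S^2 = Sf^2 * Ss^2:

    J(w) = (2/5) [ S^2 tau_m / (1 + (w tau_m)^2)
                 + (Sf^2 - S^2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_m + 1/tau_e,            Sf^2 = 1 for the simple form.

The five standard per-residue models are
    M1: {S^2}        M2: {S^2, tau_e}      M3: {S^2, Rex}
    M4: {S^2, tau_e, Rex}                  M5: {Sf^2, S^2, tau_e},
fit per residue by weighted least squares from a deterministic multi-start
grid, with the winner chosen by AIC (default) or by nested F-tests.

Rate expressions combine the N-H dipolar coupling and the axially symmetric
15N CSA:

    d = (mu0/4pi) hbar gammaH gammaN / rNH^3,      c = |wN| dsigma / sqrt(3)
    R1  = (d^2/4) [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)
    R2  = (d^2/8) [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
          + (c^2/6) [4 J(0) + 3 J(wN)] + Rex
    NOE = 1 + (d^2/4) (gammaH/gammaN) [6 J(wH+wN) - J(wH-wN)] / R1.

Defaults rNH = 1.02 A and dsigma = -172 ppm follow common 15N relaxation
practice and are configurable.  Times are ns (tau_m) and ps (tau_e) at the
API surface, seconds internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .core_io import RelaxationDataset, ResidueRange

__all__ = [
    "SpinParameters",
    "DynamicsParams",
    "ResidueFit",
    "ModelFreeFit",
    "spectral_density",
    "predict_rates",
    "estimate_tm",
    "fit_residue",
    "fit_dataset",
    "s2_threshold",
]

# physical constants (SI)
MU0_4PI = 1e-7           # T m / A
HBAR = 1.054571817e-34   # J s
GAMMA_H = 2.6752218744e8     # rad s^-1 T^-1
GAMMA_N = -2.71261804e7      # rad s^-1 T^-1 (15N, negative)

MODEL_PARAMS = {
    "M1": ("S2",),
    "M2": ("S2", "tau_e"),
    "M3": ("S2", "Rex"),
    "M4": ("S2", "tau_e", "Rex"),
    "M5": ("Sf2", "S2", "tau_e"),
}

DEFAULT_ERROR_FLOORS = {"R1": 0.02, "R2": 0.02, "NOE": 0.03}


@dataclass(frozen=True)
class SpinParameters:
    """Interaction constants for the 15N-1H spin pair."""

    rnh: float = 1.02          # N-H bond length, angstrom
    csa: float = -172.0        # 15N chemical shift anisotropy, ppm
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    field_mhz: float = 500.0   # 1H resonance frequency

    @property
    def omega_h(self) -> float:
        """1H angular frequency magnitude (rad/s)."""
        return 2.0 * math.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency magnitude (rad/s)."""
        return self.omega_h * abs(self.gamma_n) / self.gamma_h

    @property
    def d(self) -> float:
        """Dipolar coupling constant magnitude (rad/s)."""
        r = self.rnh * 1e-10
        return MU0_4PI * HBAR * self.gamma_h * abs(self.gamma_n) / r**3

    @property
    def c(self) -> float:
        """CSA coupling constant magnitude (rad/s)."""
        return abs(self.csa) * 1e-6 * self.omega_n / math.sqrt(3.0)


@dataclass(frozen=True)
class DynamicsParams:
    """Per-residue model-free dynamics parameters.

    tau_m in ns, tau_e in ps, Rex in s^-1; Sf2 is the fast-motion amplitude
    of the extended model (1.0 collapses M5 to the simple form).
    Diffusion is isotropic by default; the axially symmetric option carries
    a D-parallel/D-perpendicular ratio and is exercised through a local
    effective tau_m per residue.
    """

    model: str = "M1"
    S2: float = 1.0
    tau_e: float = 0.0
    Rex: float = 0.0
    Sf2: float = 1.0
    tau_m: float = 8.0
    diffusion: str = "isotropic"
    d_ratio: float = 1.0  # D_par / D_perp for axially symmetric diffusion

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.S2 <= 1.0 and 0.0 <= self.Sf2 <= 1.0):
            raise ValueError("order parameters must lie in [0, 1]")
        if self.S2 > self.Sf2 + 1e-12:
            raise ValueError("S2 = Sf2*Ss2 cannot exceed Sf2")
        if self.tau_e < 0 or self.Rex < 0 or self.tau_m <= 0:
            raise ValueError("tau_e, Rex must be >= 0 and tau_m > 0")
        if self.diffusion not in ("isotropic", "axial"):
            raise ValueError("diffusion must be 'isotropic' or 'axial'")

    @property
    def Ss2(self) -> float:
        return self.S2 / self.Sf2 if self.Sf2 > 0 else 0.0


def _effective_tm_s(p: DynamicsParams, angle: float = 0.0) -> float:
    """Local tumbling time in seconds.

    For axially symmetric diffusion the single-Lorentzian local
    approximation is used: tau_m(theta) from the orientation-weighted mix of
    the three axial correlation times.  With d_ratio = 1 this reduces
    exactly to the isotropic tau_m.
    """
    tm = p.tau_m * 1e-9
    if p.diffusion == "isotropic" or p.d_ratio == 1.0:
        return tm
    # D_iso fixed by tau_m = 1/(6 D_iso); split into D_par, D_perp
    d_iso = 1.0 / (6.0 * tm)
    d_perp = 3.0 * d_iso / (2.0 + p.d_ratio)
    d_par = p.d_ratio * d_perp
    taus = np.array([
        1.0 / (6.0 * d_perp),
        1.0 / (5.0 * d_perp + d_par),
        1.0 / (2.0 * d_perp + 4.0 * d_par),
    ])
    ct = math.cos(angle)
    amps = np.array([
        0.25 * (3.0 * ct**2 - 1.0) ** 2,
        3.0 * ct**2 * (1.0 - ct**2),
        0.75 * (1.0 - ct**2) ** 2,
    ])
    return float((amps * taus).sum() / amps.sum())


def spectral_density(p: DynamicsParams, omega: float | np.ndarray,
                     angle: float = 0.0) -> float | np.ndarray:
    """Model-free spectral density J(omega) in s/rad."""
    tm = _effective_tm_s(p, angle)
    te = p.tau_e * 1e-12
    w = np.asarray(omega, dtype=float)
    j = p.S2 * tm / (1.0 + (w * tm) ** 2)
    if p.Sf2 - p.S2 > 0 and te > 0:
        tp = tm * te / (tm + te)
        j = j + (p.Sf2 - p.S2) * tp / (1.0 + (w * tp) ** 2)
    out = 0.4 * j
    return float(out) if np.isscalar(omega) else out


def predict_rates(p: DynamicsParams, spin: SpinParameters,
                  angle: float = 0.0) -> tuple[float, float, float]:
    """Forward-model (R1, R2, NOE) for one residue.

    Rex adds to R2 only; R1 and the NOE are exchange-free.
    """
    wh, wn = spin.omega_h, spin.omega_n
    j0, jn, jhmn, jh, jhpn = (
        spectral_density(p, w, angle) for w in (0.0, wn, wh - wn, wh, wh + wn)
    )
    d2, c2 = spin.d**2, spin.c**2
    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + p.Rex
    sigma = (d2 / 4.0) * (6.0 * jhpn - jhmn)
    noe = 1.0 + (spin.gamma_h / spin.gamma_n) * sigma / r1
    return float(r1), float(r2), float(noe)


# ---------------------------------------------------------------------------
# global tumbling time
# ---------------------------------------------------------------------------

def _rigid_r2_over_r1(tau_m_ns: float, spin: SpinParameters) -> float:
    p = DynamicsParams(model="M1", S2=1.0, tau_m=tau_m_ns)
    r1, r2, _ = predict_rates(p, spin)
    return r2 / r1


def estimate_tm(
    ds: RelaxationDataset,
    trim: float = 0.1,
    noe_cutoff: float = 0.65,
    spin: SpinParameters | None = None,
    tm_bounds: tuple[float, float] = (0.5, 50.0),
) -> float:
    """Initial global tau_m (ns) from the trimmed-mean R2/R1 ratio.

    Only residues rigid enough for the R2/R1 relation to hold are used
    (NOE >= noe_cutoff); a symmetric `trim` fraction is cut from each tail
    of the ratio distribution to shed residual exchange outliers, and the
    rigid isotropic relation R2/R1(tau_m) is inverted by 1-D root finding.
    In the rigid (tau_e = 0, Rex = 0) limit the ratio is independent of S^2,
    which is why no order parameter is needed here.
    """
    spin = spin or SpinParameters(field_mhz=ds.field_mhz)
    spin = replace(spin, field_mhz=ds.field_mhz)
    df = ds.data
    ok = np.isfinite(df["R1"]) & np.isfinite(df["R2"]) & np.isfinite(df["NOE"])
    ok &= df["NOE"] >= noe_cutoff
    ratios = (df.loc[ok, "R2"] / df.loc[ok, "R1"]).to_numpy(dtype=float)
    if ratios.size < 5:
        raise ValueError(
            f"only {ratios.size} rigid residues (NOE >= {noe_cutoff}); "
            "supply tau_m manually")
    ratios.sort()
    ncut = int(trim * ratios.size)
    target = float(ratios[ncut: ratios.size - ncut].mean()) if ncut else float(ratios.mean())
    lo, hi = tm_bounds
    flo = _rigid_r2_over_r1(lo, spin) - target
    fhi = _rigid_r2_over_r1(hi, spin) - target
    if flo * fhi > 0:
        raise ValueError(f"R2/R1 = {target:.2f} outside invertible tau_m range {tm_bounds}")
    return float(brentq(lambda tm: _rigid_r2_over_r1(tm, spin) - target, lo, hi,
                        xtol=1e-6))


# ---------------------------------------------------------------------------
# per-residue fitting
# ---------------------------------------------------------------------------

@dataclass
class ResidueFit:
    residue: int
    model: str
    params: DynamicsParams
    chi2: float
    n_params: int
    aic: float
    converged: bool
    param_errors: dict = field(default_factory=dict)
    chi2_by_model: dict = field(default_factory=dict)


_GRID_S2 = (0.3, 0.5, 0.7, 0.85, 0.95)
_GRID_TE = (0.0, 20.0, 100.0, 500.0)   # ps
_GRID_REX = (0.0, 2.0, 5.0)            # s^-1
_BOUNDS = {"S2": (0.0, 1.0), "tau_e": (0.0, 5000.0),
           "Rex": (0.0, 50.0), "Sf2": (0.0, 1.0)}


def _make_params(model: str, x: np.ndarray, tau_m: float) -> DynamicsParams:
    names = MODEL_PARAMS[model]
    kw = dict(zip(names, (float(v) for v in x)))
    if model == "M5":
        # ensure S2 <= Sf2 inside the optimizer's box
        kw["S2"] = min(kw["S2"], kw["Sf2"])
    return DynamicsParams(model=model, tau_m=tau_m, **kw)


def _residuals(x, model, tau_m, spin, obs, err):
    p = _make_params(model, x, tau_m)
    pred = predict_rates(p, spin)
    return (np.array(pred) - obs) / err


def _starts(model: str) -> list[tuple[float, ...]]:
    """Deterministic multi-start grid per model (tau_e kept off its bound)."""
    axes = []
    for n in MODEL_PARAMS[model]:
        if n == "tau_e":
            axes.append((1.0, 20.0, 100.0, 500.0))
        elif n == "Rex":
            axes.append(_GRID_REX)
        elif n == "Sf2":
            axes.append((0.8, 0.95))
        else:
            axes.append(_GRID_S2)
    out = [()]
    for ax in axes:
        out = [s + (v,) for s in out for v in ax]
    return out


def fit_residue(
    record: dict,
    tau_m: float,
    spin: SpinParameters,
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5"),
    criterion: str = "AIC",
) -> ResidueFit:
    """Fit one residue's (R1, R2, NOE) to the standard models.

    `record` maps {'residue', 'R1', 'R2', 'NOE'} plus optional *_err keys;
    missing errors fall back to fractional floors (2%/2%/3%).  Model
    selection by AIC = chi2 + 2k (default) or by nested F-tests at
    alpha = 0.05 starting from M1.
    """
    obs = np.array([record["R1"], record["R2"], record["NOE"]], dtype=float)
    if not np.all(np.isfinite(obs)):
        return ResidueFit(int(record["residue"]), "none",
                          DynamicsParams(tau_m=tau_m), math.inf, 0, math.inf, False)
    err = np.array([
        record.get("R1_err") or DEFAULT_ERROR_FLOORS["R1"] * abs(obs[0]),
        record.get("R2_err") or DEFAULT_ERROR_FLOORS["R2"] * abs(obs[1]),
        record.get("NOE_err") or DEFAULT_ERROR_FLOORS["NOE"] * max(abs(obs[2]), 0.1),
    ], dtype=float)
    err = np.where(np.isfinite(err) & (err > 0),
                   err, DEFAULT_ERROR_FLOORS["R1"] * np.maximum(np.abs(obs), 0.1))

    fits: dict[str, tuple[float, np.ndarray, np.ndarray]] = {}
    for model in models:
        names = MODEL_PARAMS[model]
        lb = np.array([_BOUNDS[n][0] for n in names])
        ub = np.array([_BOUNDS[n][1] for n in names])
        # cheap grid scan, then gradient refinement from the best few starts
        scored = sorted(
            (float((_residuals(np.array(s), model, tau_m, spin, obs, err) ** 2).sum()), s)
            for s in _starts(model)
        )
        best = None
        for _, start in scored[:3]:
            x0 = np.clip(np.array(start, dtype=float), lb + 1e-9, ub - 1e-9)
            try:
                sol = least_squares(
                    _residuals, x0, bounds=(lb, ub),
                    args=(model, tau_m, spin, obs, err),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
                )
            except Exception:
                continue
            chi2 = float(2.0 * sol.cost)
            if best is None or chi2 < best[0] - 1e-15:
                best = (chi2, sol.x, sol.jac)
        if best is not None:
            fits[model] = best

    if not fits:
        return ResidueFit(int(record["residue"]), "none",
                          DynamicsParams(tau_m=tau_m), math.inf, 0, math.inf, False)

    chi2_by_model = {m: f[0] for m, f in fits.items()}
    if criterion.upper() == "AIC":
        chosen = min(fits, key=lambda m: (fits[m][0] + 2 * len(MODEL_PARAMS[m]),
                                          len(MODEL_PARAMS[m])))
    else:
        chosen = _select_ftest(fits)

    chi2, x, jac = fits[chosen]
    params = _make_params(chosen, x, tau_m)
    errors = _covariance_errors(jac, MODEL_PARAMS[chosen])
    k = len(MODEL_PARAMS[chosen])
    return ResidueFit(int(record["residue"]), chosen, params, chi2, k,
                      chi2 + 2 * k, True, errors, chi2_by_model)


def _select_ftest(fits: dict, alpha: float = 0.05) -> str:
    """Nested F-test ladder: accept extra parameters only on significant drops."""
    from scipy.stats import f as f_dist

    ndata = 3

    def better(simple: str, complex_: str) -> bool:
        if complex_ not in fits or simple not in fits:
            return False
        c_s, c_c = fits[simple][0], fits[complex_][0]
        k_s, k_c = len(MODEL_PARAMS[simple]), len(MODEL_PARAMS[complex_])
        dof_c = ndata - k_c
        if dof_c <= 0:
            # saturated model: require near-exact fit improvement
            return c_c < c_s * 1e-3
        if c_c <= 0:
            return True
        fstat = ((c_s - c_c) / (k_c - k_s)) / (c_c / dof_c)
        return fstat > f_dist.ppf(1 - alpha, k_c - k_s, dof_c)

    chosen = "M1" if "M1" in fits else min(fits, key=lambda m: len(MODEL_PARAMS[m]))
    for step in ("M2", "M3"):
        if better(chosen, step):
            chosen = step
            break
    for step in ("M4", "M5"):
        if better(chosen, step):
            chosen = step
            break
    return chosen


def _covariance_errors(jac: np.ndarray, names: tuple[str, ...]) -> dict:
    try:
        cov = np.linalg.inv(jac.T @ jac)
        return {n: float(math.sqrt(max(cov[i, i], 0.0)))
                for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        return {}


# ---------------------------------------------------------------------------
# dataset-level analysis
# ---------------------------------------------------------------------------

@dataclass
class ModelFreeFit:
    residues: list[ResidueFit]
    tau_m: float
    diffusion: str
    range: ResidueRange
    s2_mean: float
    s2_sd: float
    flexible_residues: list[int]
    flexibility_threshold: float

    def as_frame(self):
        import pandas as pd
        rows = []
        for r in self.residues:
            rows.append({
                "residue": r.residue, "model": r.model, "S2": r.params.S2,
                "tau_e_ps": r.params.tau_e, "Rex": r.params.Rex,
                "Sf2": r.params.Sf2, "chi2": r.chi2, "converged": r.converged,
            })
        return pd.DataFrame(rows)


def s2_threshold(mean: float, sd: float, k: float = 2.0) -> float:
    """Flexibility cutoff mean - k*SD of the order-parameter distribution.

    Residues at or below this value are substantially more mobile on the
    ps-ns timescale than the molecular average.
    """
    return mean - k * sd


def fit_dataset(
    ds: RelaxationDataset,
    rng: ResidueRange,
    criterion: str = "AIC",
    tau_m: float | None = None,
    spin: SpinParameters | None = None,
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5"),
    flex_k: float = 2.0,
) -> ModelFreeFit:
    """Full model-free analysis over a residue window.

    tau_m is estimated from R2/R1 when not supplied; the summary mean and SD
    of S^2 include only converged residues inside the window, and the
    flexible-residue list applies the mean - flex_k*SD threshold.
    """
    sub = ds.select_range(rng)
    spin = replace(spin or SpinParameters(), field_mhz=ds.field_mhz)
    tm = float(tau_m) if tau_m is not None else estimate_tm(ds, spin=spin)
    fits = [
        fit_residue(row._asdict() if hasattr(row, "_asdict") else dict(row),
                    tm, spin, models=models, criterion=criterion)
        for row in sub.data.to_dict("records")
    ]
    s2 = np.array([f.params.S2 for f in fits if f.converged])
    if s2.size == 0:
        raise ValueError("no residue converged; cannot summarize S2")
    mean, sd = float(s2.mean()), float(s2.std())
    thr = s2_threshold(mean, sd, flex_k)
    flex = sorted(f.residue for f in fits if f.converged and f.params.S2 <= thr)
    return ModelFreeFit(fits, tm, "isotropic", rng, mean, sd, flex, thr)
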