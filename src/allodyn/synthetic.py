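"""Ground-truthed synthetic inputs for every analysis stage.

Real MD trajectories and spectra come without a known answer; these
generators produce inputs whose perturbations are implanted by
construction, so recovery can be asserted exactly.

Trajectories come from a Gaussian network model (GNM): residues are nodes
of a spring network built on a reference chain, and each frame draws
independent Gaussian displacements whose per-axis covariance is the
pseudo-inverse of the spring-weighted contact Laplacian.  Binding is
emulated by multiplying the spring constants of contacts touching a
"binding site" (stiffening quenches distance fluctuations there) and a
distal "allosteric" region (softening enhances strain there).  Because the
target covariance is known analytically, the fluctuation analyses have
exact ground truth; what the GNM does not emulate is anharmonicity, frame-
to-frame kinetics, and solvent.

Relaxation datasets are forward-modeled through the same rate expressions
the fitter inverts (known per-residue S^2, tau_e, Rex under a global tau_m)
plus Gaussian noise; R1rho is generated as exchange-free R2, the idealized
fully-spin-locked limit.  Peak tables implant chemical-shift and intensity
perturbations at designated residues.

Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .core_io import PeakTable, RelaxationDataset, Trajectory
from .modelfree import DynamicsParams, SpinParameters, predict_rates

__all__ = [
    "GNMSpec",
    "RelaxSpec",
    "PeakSpec",
    "helix_chain",
    "compact_chain",
    "gnm_trajectory",
    "gnm_covariance",
    "generate_relaxation",
    "generate_peak_tables",
    "default_apo_holo_specs",
]

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

# Default fixture mirrors a 131-residue folded core numbered 25-155.
DEFAULT_FIRST_RESIDUE = 25
DEFAULT_N_RESIDUES = 131


def helix_chain(n: int, radius: float = 2.3, rise: float = 1.5,
                turn_deg: float = 100.0) -> np.ndarray:
    """An extended helical chain with ~3.8 A CA spacing (quasi-1D contacts).

    Useful for fixtures where sequence-local contact topology is wanted;
    note that a quasi-1D network delocalizes spring perturbations (the two
    halves hinge about any softened joint), so the default reference for
    perturbation-recovery fixtures is the compact chain instead.
    """
    t = np.arange(n) * np.deg2rad(turn_deg)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            rise * np.arange(n)]).astype(float)


def compact_chain(n: int, spacing: float = 3.8) -> np.ndarray:
    """Reference fold: a compact self-avoiding chain on a cubic lattice.

    A boustrophedon (serpentine) walk filling the smallest cube that holds
    n residues, scaled to the canonical 3.8 A CA-CA step.  The walk is
    self-avoiding and globular, so the contact network has the redundant,
    well-connected topology of a folded domain and spring perturbations
    stay local — the property the recovery fixtures rely on.
    """
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    row = 0  # global row parity keeps every step one lattice unit
    for z in range(side):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for y in ys:
            xs = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
            row += 1
            for x in xs:
                pts.append((x, y, z))
                if len(pts) == n:
                    return np.asarray(pts, dtype=float) * spacing
    return np.asarray(pts[:n], dtype=float) * spacing


@dataclass(frozen=True)
class GNMSpec:
    """Spring-network trajectory specification.

    perturbations: list of (residue-id tuple, spring multiplier); the
    multiplier applies to every contact incident to a listed residue
    (multiplier > 1 stiffens, < 1 softens).  amplitude (angstrom) scales the
    displacement field: per-axis covariance = amplitude^2 * pinv(Laplacian).
    """

    n_residues: int = DEFAULT_N_RESIDUES
    first_residue: int = DEFAULT_FIRST_RESIDUE
    cutoff: float = 7.5
    base_spring: float = 1.0
    perturbations: tuple = ()
    amplitude: float = 1.0
    n_frames: int = 2000
    seed: int = 0
    coords: np.ndarray | None = None  # optional externally supplied reference

    @property
    def residue_ids(self) -> np.ndarray:
        return self.first_residue + np.arange(self.n_residues)

    def reference(self) -> np.ndarray:
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (self.n_residues, 3):
                raise ValueError("supplied reference coords have wrong shape")
            return c
        return compact_chain(self.n_residues)


def _weighted_laplacian(spec: GNMSpec) -> np.ndarray:
    ids = spec.residue_ids
    ref = spec.reference()
    diff = ref[:, None, :] - ref[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    contacts = (dist <= spec.cutoff) & ~np.eye(spec.n_residues, dtype=bool)
    weights = np.where(contacts, spec.base_spring, 0.0)
    for res_set, mult in spec.perturbations:
        if mult <= 0:
            raise ValueError("spring multipliers must be > 0")
        res_arr = np.asarray(res_set, dtype=int)
        if not np.isin(res_arr, ids).all():
            raise ValueError("perturbation residues outside the chain")
        members = np.isin(ids, res_arr)
        touch = members[:, None] | members[None, :]
        weights = np.where(contacts & touch, weights * mult, weights)
    n_comp, _ = connected_components((weights > 0).astype(int), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"contact graph has {n_comp} components at cutoff {spec.cutoff}; "
            "covariance ill-defined across components")
    return np.diag(weights.sum(axis=1)) - weights


def gnm_covariance(spec: GNMSpec) -> np.ndarray:
    """Target per-axis displacement covariance amplitude^2 * pinv(L)."""
    lap = _weighted_laplacian(spec)
    evals, evecs = np.linalg.eigh(lap)
    tol = evals[-1] * 1e-10
    nonzero = evals > tol
    if (~nonzero).sum() != 1:
        raise ValueError("Laplacian must have exactly one zero mode")
    inv = np.zeros_like(evals)
    inv[nonzero] = 1.0 / evals[nonzero]
    return spec.amplitude**2 * (evecs * inv) @ evecs.T


def gnm_trajectory(spec: GNMSpec) -> Trajectory:
    """Sample frames of reference + correlated Gaussian displacements.

    Displacements are i.i.d. across frames and across the three axes, each
    axis with the spec's target covariance, so the trajectory is stationary
    by construction and the known covariance is the analytic ground truth
    for the fluctuation observables.
    """
    lap = _weighted_laplacian(spec)
    evals, evecs = np.linalg.eigh(lap)
    tol = evals[-1] * 1e-10
    nz = evals > tol
    if (~nz).sum() != 1:
        raise ValueError("Laplacian must have exactly one zero mode")
    scale = spec.amplitude / np.sqrt(evals[nz])
    basis = evecs[:, nz]  # (n, n-1)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, nz.sum()))
    disp = np.einsum("fak,nk->fna", z * scale, basis)
    coords = spec.reference()[None, :, :] + disp
    return Trajectory(coords, spec.residue_ids, atom_selection="CA")


def default_apo_holo_specs(
    seed: int = 0,
    site: tuple[int, ...] = (128, 129, 130, 131, 132),
    distal: tuple[int, ...] = (66, 67, 68, 69),
    stiffen: float = 5.0,
    soften: float = 0.3,
    n_frames: int = 2000,
) -> tuple[GNMSpec, GNMSpec]:
    """Paired apo/holo specs differing only by the binding perturbation.

    The holo state stiffens the contacts of a 5-residue binding site by 5x
    and softens those of a 4-residue distal region (multiplier 0.3),
    emulating direct rigidification at the ligand site and an allosteric
    loosening far from it; the softening multiplier is chosen so the two
    implants perturb the fluctuation matrix with comparable magnitude.
    Apo and holo use offset seeds so their frames are independent draws.
    """
    apo = GNMSpec(n_frames=n_frames, seed=seed)
    holo = replace(apo, perturbations=((site, stiffen), (distal, soften)),
                   seed=seed + 1_000_000)
    return apo, holo


# ---------------------------------------------------------------------------
# relaxation data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxSpec:
    """Forward-model relaxation dataset with known per-residue truth."""

    truth: tuple  # tuple of (residue_id, DynamicsParams)
    field_mhz: float = 500.0
    noise: dict = field(default_factory=lambda: {
        "R1": 0.02, "R2": 0.02, "NOE": 0.03, "R1rho": 0.02})
    include_r1rho: bool = True
    seed: int = 0
    spin: SpinParameters = SpinParameters()


def flat_profile_truth(
    residue_ids: np.ndarray | list[int],
    s2: float = 0.85,
    tau_m: float = 8.0,
    tau_e: float = 50.0,
    flexible: dict | None = None,
    rex: dict | None = None,
) -> tuple:
    """Convenience truth: rigid core with optional flexible/exchanging residues.

    flexible maps residue -> S2 override (model M2), rex maps residue ->
    Rex in s^-1 (model M4 when combined with tau_e, else M3).
    """
    flexible = flexible or {}
    rex = rex or {}
    truth = []
    for rid in residue_ids:
        rid = int(rid)
        s2_i = float(flexible.get(rid, s2))
        rex_i = float(rex.get(rid, 0.0))
        if rex_i > 0 and tau_e > 0:
            model = "M4"
        elif rex_i > 0:
            model = "M3"
        elif tau_e > 0:
            model = "M2"
        else:
            model = "M1"
        truth.append((rid, DynamicsParams(model=model, S2=s2_i, tau_e=tau_e,
                                          Rex=rex_i, tau_m=tau_m)))
    return tuple(truth)


def generate_relaxation(spec: RelaxSpec) -> RelaxationDataset:
    """Rates = predict_rates(truth) + Gaussian noise at the stated fractions.

    Error columns carry the exact noise SDs used, so downstream weighted
    fits are correctly calibrated.  R1rho is the exchange-free transverse
    rate (Rex fully quenched by the spin lock).
    """
    rng = np.random.default_rng(spec.seed)
    spin = replace(spec.spin, field_mhz=spec.field_mhz)
    rows = []
    for rid, p in spec.truth:
        r1, r2, noe = predict_rates(p, spin)
        r1rho = predict_rates(replace(p, Rex=0.0), spin)[1]
        e = {
            "R1": spec.noise.get("R1", 0.0) * r1,
            "R2": spec.noise.get("R2", 0.0) * r2,
            "NOE": spec.noise.get("NOE", 0.0) * max(abs(noe), 0.1),
            "R1rho": spec.noise.get("R1rho", 0.0) * r1rho,
        }
        z = rng.standard_normal(4)
        row = {
            "residue": int(rid),
            "R1": r1 + e["R1"] * z[0],
            "R2": r2 + e["R2"] * z[1],
            "NOE": noe + e["NOE"] * z[2],
            "R1_err": e["R1"] if e["R1"] > 0 else np.nan,
            "R2_err": e["R2"] if e["R2"] > 0 else np.nan,
            "NOE_err": e["NOE"] if e["NOE"] > 0 else np.nan,
        }
        if spec.include_r1rho:
            row["R1rho"] = r1rho + e["R1rho"] * z[3]
            row["R1rho_err"] = e["R1rho"] if e["R1rho"] > 0 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    meta = {"generator": "allodyn.synthetic.generate_relaxation",
            "rng": RNG_ALGORITHM, "seed": str(spec.seed)}
    return RelaxationDataset(df, field_mhz=spec.field_mhz, meta=meta)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """Apo/holo HSQC-style peak tables with implanted perturbations.

    shifts: residue -> (ddH, ddN) added to the holo resonance positions;
    apo_intensity / holo_intensity: residue -> multiplicative scale on the
    unit baseline (e.g. apo 0.2 recovering to holo 1.0 emulates a peak
    broadened by exchange in the apo state that sharpens upon binding).
    shift_noise in ppm (same for 1H; 15N scaled 5x), intensity_noise as a
    fraction of the baseline.
    """

    residue_ids: tuple = tuple(range(25, 156))
    shifts: dict = field(default_factory=dict)
    apo_intensity: dict = field(default_factory=dict)
    holo_intensity: dict = field(default_factory=dict)
    shift_noise: float = 0.0
    intensity_noise: float = 0.0
    seed: int = 0


def generate_peak_tables(spec: PeakSpec) -> tuple[PeakTable, PeakTable]:
    rng = np.random.default_rng(spec.seed)
    ids = np.array(sorted(int(r) for r in spec.residue_ids))
    n = ids.size
    dh = rng.uniform(7.0, 10.0, n)
    dn = rng.uniform(105.0, 130.0, n)
    base_i = rng.lognormal(mean=0.0, sigma=0.15, size=n)

    def noise(scale: float, size: int) -> np.ndarray:
        return rng.standard_normal(size) * scale if scale > 0 else np.zeros(size)

    apo = pd.DataFrame({
        "residue": ids,
        "dH": dh + noise(spec.shift_noise, n),
        "dN": dn + noise(5.0 * spec.shift_noise, n),
        "intensity": np.clip(
            base_i * np.array([spec.apo_intensity.get(int(r), 1.0) for r in ids])
            * (1.0 + noise(spec.intensity_noise, n)), 0.0, None),
    })
    ddh = np.array([spec.shifts.get(int(r), (0.0, 0.0))[0] for r in ids])
    ddn = np.array([spec.shifts.get(int(r), (0.0, 0.0))[1] for r in ids])
    holo = pd.DataFrame({
        "residue": ids,
        "dH": dh + ddh + noise(spec.shift_noise, n),
        "dN": dn + ddn + noise(5.0 * spec.shift_noise, n),
        "intensity": np.clip(
            base_i * np.array([spec.holo_intensity.get(int(r), 1.0) for r in ids])
            * (1.0 + noise(spec.intensity_noise, n)), 0.0, None),
    })
    meta = {"generator": "allodyn.synthetic.generate_peak_tables",
            "rng": RNG_ALGORITHM, "seed": str(spec.seed)}
    return PeakTable(apo, meta=dict(meta)), PeakTable(holo, meta=dict(meta))
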