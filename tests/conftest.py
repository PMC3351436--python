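"""Shared fixtures: tiny trajectories and tables built in memory or on tmp_path."""

import numpy as np
import pandas as pd
import pytest

from allodyn.core_io import PeakTable, RelaxationDataset, Trajectory


@pytest.fixture
def random_trajectory():
    """Factory: n-residue, f-frame trajectory with reproducible jitter."""

    def make(n_residues=5, n_frames=20, seed=0, first_id=1, spread=0.5):
        rng = np.random.default_rng(seed)
        ref = np.cumsum(rng.normal(0, 2.0, size=(n_residues, 3)), axis=0)
        coords = ref[None] + rng.normal(0, spread, size=(n_frames, n_residues, 3))
        ids = np.arange(first_id, first_id + n_residues)
        return Trajectory(coords, ids)

    return make


@pytest.fixture
def peak_table_factory():
    def make(residues, dh=None, dn=None, intensity=None, sidechain=None):
        n = len(residues)
        return PeakTable(pd.DataFrame({
            "residue": residues,
            "dH": dh if dh is not None else np.linspace(7.0, 9.0, n),
            "dN": dn if dn is not None else np.linspace(110.0, 125.0, n),
            "intensity": intensity if intensity is not None else np.ones(n),
            "sidechain": sidechain if sidechain is not None else [False] * n,
        }))

    return make


@pytest.fixture
def relaxation_factory():
    def make(residues, r1=1.5, r2=12.0, noe=0.8, r1rho=None, field=500.0, **errs):
        n = len(residues)

        def col(v):
            return np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, dtype=float)

        data = {"residue": residues, "R1": col(r1), "R2": col(r2), "NOE": col(noe)}
        if r1rho is not None:
            data["R1rho"] = col(r1rho)
        for k, v in errs.items():
            data[k] = col(v)
        return RelaxationDataset(pd.DataFrame(data), field_mhz=field)

    return make
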