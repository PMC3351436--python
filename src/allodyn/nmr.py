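"""Per-residue apo/holo NMR perturbation metrics.

Four complementary probes of how ligand binding perturbs a protein:

* chemical shift perturbation (CSP): weighted combination of amide 1H and
  15N shift changes, Dd_comb = sqrt(DdH^2 + (alpha*DdN)^2), reporting direct
  contact and local structural rearrangement;
* HSQC cross-peak intensity changes: normalized intensity ratios, sensitive
  to exchange broadening (a low apo peak recovering to the molecular average
  upon binding signals quenched conformational exchange);
* R2/R1rho ratios: values significantly above one flag microsecond to
  millisecond conformational exchange, because the spin-lock of R1rho
  refocuses exchange broadening that is present in R2;
* water-selective (ePHOGSY-type) NOE/ROE intensities: classify residues by
  proximity to long-lived hydration water, with the ROE channel guarding
  against chemical-exchange relay artefacts.

Peaks missing in one state are reported as 'disappeared'/'appeared' rather
than as a zero or infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PeakTable, RelaxationDataset

__all__ = [
    "CSPRecord",
    "IntensityChange",
    "ExchangeFlag",
    "HydrationRecord",
    "DEFAULT_ALPHA",
    "csp",
    "csp_significance",
    "intensity_change",
    "exchange_flags",
    "ephogsy_classify",
]

# 15N weighting in the combined shift; standard gyromagnetic-ratio-derived
# scaling used with amide CSP mapping.
DEFAULT_ALPHA = 0.154


@dataclass
class CSPRecord:
    residue: int
    delta_h: float
    delta_n: float
    combined: float
    significant: bool = False
    sidechain: bool = False


@dataclass
class IntensityChange:
    residue: int
    i_apo_norm: float
    i_holo_norm: float
    ratio: float          # NaN when either side missing
    category: str         # increased | decreased | unchanged | disappeared | appeared | missing
    sidechain: bool = False


@dataclass
class ExchangeFlag:
    residue: int
    ratio: float          # R2 / R1rho
    error: float          # propagated, NaN when input errors absent
    flagged: bool


@dataclass
class HydrationRecord:
    residue: int
    noe_apo: float
    noe_holo: float
    roe_apo: float
    roe_holo: float
    noe_class: str        # high | medium | low (apo intensity class)
    roe_class: str
    noe_changed: bool
    roe_changed: bool
    water_proximal: bool  # high NOE without a confounding ROE correlation


# ---------------------------------------------------------------------------
# chemical shift perturbation
# ---------------------------------------------------------------------------

def csp(apo: PeakTable, holo: PeakTable, alpha: float = DEFAULT_ALPHA) -> list[CSPRecord]:
    """Combined and separate chemical shift changes per matched residue.

    Residues are matched by id within the backbone and side-chain groups
    separately; residues present in only one table are skipped.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    merged = pd.merge(
        apo.data, holo.data, on=["residue", "sidechain"],
        suffixes=("_apo", "_holo"), how="inner",
    )
    if merged.empty:
        raise ValueError("apo and holo peak tables share no residues")
    out = []
    for row in merged.itertuples(index=False):
        dh = row.dH_holo - row.dH_apo
        dn = row.dN_holo - row.dN_apo
        comb = float(np.hypot(dh, alpha * dn))
        out.append(CSPRecord(int(row.residue), float(dh), float(dn), comb,
                             sidechain=bool(row.sidechain)))
    out.sort(key=lambda r: (r.sidechain, r.residue))
    return out


def csp_significance(
    records: list[CSPRecord],
    method: str = "mean_sd",
    k: float = 3.0,
    cutoff: float | None = None,
) -> list[CSPRecord]:
    """Flag significantly perturbed residues (in place; records returned).

    'mean_sd': iteratively exclude residues whose combined shift exceeds
    mean + k*SD of the remainder, until the flagged set is stable — the
    usual way a CSP baseline is freed from the perturbed sites themselves.
    'fixed': flag combined shift > cutoff.
    """
    vals = np.array([r.combined for r in records], dtype=float)
    if method == "fixed":
        if cutoff is None:
            raise ValueError("fixed method needs a cutoff")
        flags = vals > cutoff
    elif method == "mean_sd":
        flags = np.zeros(vals.size, dtype=bool)
        for _ in range(vals.size):
            base = vals[~flags]
            if base.size == 0 or base.std() == 0:
                break
            thr = base.mean() + k * base.std()
            new = vals > thr
            if np.array_equal(new, flags):
                break
            flags = new
    else:
        raise ValueError(f"unknown method {method!r}")
    for r, f in zip(records, flags):
        r.significant = bool(f)
    return records


# ---------------------------------------------------------------------------
# intensity changes
# ---------------------------------------------------------------------------

def _normalizer(values: np.ndarray, norm: str) -> float:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite intensities to normalize by")
    stat = {"mean": np.mean, "median": np.median}.get(norm)
    if stat is None:
        raise ValueError(f"unknown normalization {norm!r}")
    z = float(stat(finite))
    if z == 0:
        raise ValueError("zero intensity normalizer")
    return z


def intensity_change(
    apo: PeakTable,
    holo: PeakTable,
    norm: str = "mean",
    up_thr: float = 1.5,
    down_thr: float = 0.67,
    reference_residues: list[int] | None = None,
) -> list[IntensityChange]:
    """Normalized per-residue intensity ratios with categorical calls.

    Each spectrum is normalized by the chosen statistic over backbone peaks
    present in both spectra (or over `reference_residues` when given);
    side-chain peaks are normalized within their own group.  The ratio is
    invariant to a global rescaling of either spectrum.
    """
    merged = pd.merge(
        apo.data, holo.data, on=["residue", "sidechain"],
        suffixes=("_apo", "_holo"), how="outer",
    ).sort_values(["sidechain", "residue"])
    out = []
    for sc in (False, True):
        grp = merged[merged["sidechain"].fillna(False).astype(bool) == sc]
        if grp.empty:
            continue
        ia = grp["intensity_apo"].to_numpy(dtype=float)
        ih = grp["intensity_holo"].to_numpy(dtype=float)
        both = np.isfinite(ia) & np.isfinite(ih)
        if reference_residues is not None:
            ref = np.isin(grp["residue"].to_numpy(dtype=int), reference_residues) & both
        else:
            ref = both
        if not ref.any():
            raise ValueError("no shared peaks to define the normalization")
        za = _normalizer(ia[ref], norm)
        zh = _normalizer(ih[ref], norm)
        for rid, a, h in zip(grp["residue"].to_numpy(dtype=int), ia / za, ih / zh):
            if np.isfinite(a) and np.isfinite(h):
                ratio = h / a
                if ratio > up_thr:
                    cat = "increased"
                elif ratio < down_thr:
                    cat = "decreased"
                else:
                    cat = "unchanged"
            elif np.isfinite(a):
                ratio, cat = np.nan, "disappeared"
            elif np.isfinite(h):
                ratio, cat = np.nan, "appeared"
            else:
                ratio, cat = np.nan, "missing"
            out.append(IntensityChange(int(rid), float(a), float(h),
                                       float(ratio), cat, sidechain=sc))
    return out


# ---------------------------------------------------------------------------
# conformational exchange from R2 / R1rho
# ---------------------------------------------------------------------------

def exchange_flags(ds: RelaxationDataset, k: float = 1.0) -> list[ExchangeFlag]:
    """Flag residues whose R2/R1rho ratio exceeds mean + k*SD of the ratios.

    The default k = 1 places the cut at one standard deviation above the
    molecular average.  Errors, when present in the dataset, propagate in
    quadrature to the ratio.  The flag set shrinks monotonically as k grows.
    """
    df = ds.data
    ok = np.isfinite(df["R2"]) & np.isfinite(df["R1rho"])
    if not ok.any():
        raise ValueError("no residue has both R2 and R1rho")
    sub = df[ok]
    ratio = (sub["R2"] / sub["R1rho"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        rel = np.sqrt(
            (sub["R2_err"].to_numpy(dtype=float) / sub["R2"].to_numpy(dtype=float)) ** 2
            + (sub["R1rho_err"].to_numpy(dtype=float) / sub["R1rho"].to_numpy(dtype=float)) ** 2
        )
    err = ratio * rel
    thr = float(ratio.mean() + k * ratio.std())
    return [
        ExchangeFlag(int(rid), float(r), float(e), bool(r > thr))
        for rid, r, e in zip(sub["residue"].to_numpy(dtype=int), ratio, err)
    ]


# ---------------------------------------------------------------------------
# hydration classification
# ---------------------------------------------------------------------------

def _classify(value: float, lo: float, hi: float) -> str:
    if not np.isfinite(value):
        return "missing"
    if value >= hi:
        return "high"
    if value >= lo:
        return "medium"
    return "low"


def _norm_intensities(table: PeakTable) -> dict[int, float]:
    bb = table.backbone
    vals = bb["intensity"].to_numpy(dtype=float)
    z = _normalizer(vals, "mean")
    return {int(r): float(v / z)
            for r, v in zip(bb["residue"], vals)}


def ephogsy_classify(
    apo_noe: PeakTable,
    apo_roe: PeakTable,
    holo_noe: PeakTable,
    holo_roe: PeakTable,
    thresholds: tuple[float, float] | None = None,
    change_frac: float = 0.5,
) -> list[HydrationRecord]:
    """Three-level hydration classes plus binding-induced change flags.

    Water-selective NOE intensities (normalized per spectrum) are binned
    into low/medium/high by two thresholds — defaults are the tertiles of
    the apo NOE distribution.  A residue's intensity 'changed' when the
    holo/apo ratio deviates from 1 by more than `change_frac` (default
    +-50%).  Residues whose ROE channel also classifies at least 'medium'
    are withheld from water-proximity claims (exchange-relay suspects) but
    stay in the record.
    """
    noe_a, noe_h = _norm_intensities(apo_noe), _norm_intensities(holo_noe)
    roe_a, roe_h = _norm_intensities(apo_roe), _norm_intensities(holo_roe)
    if thresholds is None:
        base = np.array([v for v in noe_a.values() if np.isfinite(v)])
        lo, hi = (float(q) for q in np.quantile(base, [1 / 3, 2 / 3]))
    else:
        lo, hi = thresholds
        if not lo < hi:
            raise ValueError("thresholds must be (low, high) with low < high")

    def changed(a: float, h: float) -> bool:
        if not (np.isfinite(a) and np.isfinite(h)) or a == 0:
            return False
        return abs(h / a - 1.0) > change_frac

    out = []
    for rid in sorted(set(noe_a) | set(noe_h)):
        na, nh = noe_a.get(rid, np.nan), noe_h.get(rid, np.nan)
        ra, rh = roe_a.get(rid, np.nan), roe_h.get(rid, np.nan)
        noe_class = _classify(na, lo, hi)
        roe_class = _classify(ra, lo, hi)
        out.append(HydrationRecord(
            residue=rid, noe_apo=float(na), noe_holo=float(nh),
            roe_apo=float(ra), roe_holo=float(rh),
            noe_class=noe_class, roe_class=roe_class,
            noe_changed=changed(na, nh), roe_changed=changed(ra, rh),
            water_proximal=(noe_class == "high" and roe_class not in ("high", "medium")),
        ))
    return out
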