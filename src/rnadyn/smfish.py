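"""Per-cell smFISH quantification.

Spots are assigned to cells and compartments from nucleus/cytoplasm
label masks, classified as transcription sites or single mRNA molecules
by intensity and localization (only nuclear spots can be transcription
sites; a cell carries at most ``max_alleles`` of them), colocalized
across channels by one-to-one nearest-neighbour matching within the
diffraction limit, and summarised as per-cell counts and probe-to-probe
Pearson correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .io import CellROI

__all__ = [
    "ColocResult",
    "CellCounts",
    "CorrelationResult",
    "assign_compartments",
    "classify_spots",
    "colocalize",
    "count_cells",
    "probe_correlation",
    "nn_distance_histogram",
]


@dataclass
class ColocResult:
    """Two-channel colocalization summary for one spot set."""

    pairs: pd.DataFrame  # spot_id_a, spot_id_b, distance_um
    nn_distances_um: np.ndarray  # nearest-neighbour distance per A spot
    fraction_colocalized: float
    radius_um: float
    n_a: int
    n_b: int
    compartment: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_colocalized <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class CellCounts:
    cell_id: int
    n_ts: int
    n_nuclear_mrna: int
    n_cytoplasmic_mrna: int
    max_alleles: int = 4

    @property
    def active_fraction(self) -> float:
        return self.n_ts / self.max_alleles


@dataclass
class CorrelationResult:
    r: float
    n: int


def assign_compartments(spots: pd.DataFrame, rois: list[CellROI],
                        *, pixel_size_um: float | None = None) -> pd.DataFrame:
    """Label each spot with the mask containing its rounded pixel position.

    ``spots`` needs ``x_um, y_um`` columns; positions are converted to
    pixels with ``pixel_size_um``.  Spots in no mask get compartment
    ``none`` and ``cell_id`` -1 (excluded from downstream counting).
    Each spot lands in at most one cell because ROI masks are disjoint.
    """
    out = pd.DataFrame(spots).copy()
    if pixel_size_um is None:
        pixel_size_um = 1.0
    compartments = []
    cell_ids = []
    for row in out.itertuples(index=False):
        px = int(round(row.x_um / pixel_size_um))
        py = int(round(row.y_um / pixel_size_um))
        comp, cid = "none", -1
        for roi in rois:
            ny, nx = roi.nucleus_mask.shape
            if not (0 <= py < ny and 0 <= px < nx):
                continue
            if roi.nucleus_mask[py, px]:
                comp, cid = "nucleus", roi.cell_id
                break
            if roi.cytoplasm_mask[py, px]:
                comp, cid = "cytoplasm", roi.cell_id
                break
        compartments.append(comp)
        cell_ids.append(cid)
    out["compartment"] = compartments
    out["cell_id"] = cell_ids
    return out


def classify_spots(
    cell_spots: pd.DataFrame,
    *,
    ts_factor: float = 2.0,
    max_alleles: int = 4,
) -> tuple[pd.DataFrame, float | None]:
    """Classify one cell's spots as transcription sites or single mRNAs.

    The single-molecule reference intensity is the median amplitude of
    the cell's cytoplasmic spots (per-cell reference, robust to
    illumination differences between cells).  Nuclear spots at or above
    ``ts_factor`` times the reference are transcription sites, capped at
    ``max_alleles`` per cell by descending amplitude; the excess is
    reclassified as single mRNA and flagged.  A cell without cytoplasmic
    spots cannot be classified and returns ``(spots with kind=NA,
    None)``.
    """
    out = pd.DataFrame(cell_spots).copy()
    out["kind"] = pd.NA
    out["capped"] = False
    cyt = out[out["compartment"] == "cytoplasm"]
    if len(cyt) == 0:
        return out, None
    reference = float(cyt["amplitude"].median())
    out.loc[out["compartment"].isin(["cytoplasm", "none"]), "kind"] = "single_mrna"
    nuc = out["compartment"] == "nucleus"
    is_ts = nuc & (out["amplitude"] >= ts_factor * reference)
    out.loc[nuc, "kind"] = "single_mrna"
    ts_idx = out.index[is_ts]
    if len(ts_idx) > max_alleles:
        order = out.loc[ts_idx, "amplitude"].sort_values(ascending=False).index
        keep = order[:max_alleles]
        dropped = order[max_alleles:]
        out.loc[keep, "kind"] = "transcription_site"
        out.loc[dropped, "kind"] = "single_mrna"
        out.loc[dropped, "capped"] = True
    else:
        out.loc[ts_idx, "kind"] = "transcription_site"
    return out, reference


def colocalize(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    radius_um: float = 0.3,
    *,
    compartment: str | None = None,
    mode: str = "matched",
) -> ColocResult:
    """Nearest-neighbour colocalization of channel A against channel B.

    Records the nearest-neighbour distance for every A spot, then
    matches A to B one-to-one greedily in ascending distance order
    (lexicographic tie-break); the colocalized fraction is the share of
    A spots with a match within ``radius_um``.  ``mode='any_neighbor'``
    instead counts any A spot whose nearest B neighbour lies within the
    radius (no one-to-one constraint).
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    a = pd.DataFrame(spots_a)
    b = pd.DataFrame(spots_b)
    if compartment is not None:
        a = a[a["compartment"] == compartment]
        b = b[b["compartment"] == compartment]
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    if len(a) == 0:
        raise ValueError("channel A has no spots to colocalize")
    pa = a[["x_um", "y_um"]].to_numpy()
    if len(b) == 0:
        nn = np.full(len(a), np.inf)
        return ColocResult(
            pairs=pd.DataFrame(columns=["spot_id_a", "spot_id_b", "distance_um"]),
            nn_distances_um=nn,
            fraction_colocalized=0.0,
            radius_um=radius_um,
            n_a=len(a),
            n_b=0,
            compartment=compartment or "all",
        )
    pb = b[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(pb)
    nn, _ = tree.query(pa, k=1)

    if mode == "any_neighbor":
        frac = float(np.mean(nn <= radius_um))
        pairs = pd.DataFrame(columns=["spot_id_a", "spot_id_b", "distance_um"])
    elif mode == "matched":
        cand = tree.query_ball_point(pa, r=radius_um)
        edges = []
        for ia, lst in enumerate(cand):
            for ib in lst:
                d = math.hypot(pa[ia, 0] - pb[ib, 0], pa[ia, 1] - pb[ib, 1])
                edges.append((d, ia, ib))
        edges.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        rows = []
        ida = a["spot_id"] if "spot_id" in a.columns else a.index
        idb = b["spot_id"] if "spot_id" in b.columns else b.index
        for d, ia, ib in edges:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            rows.append({"spot_id_a": ida.iloc[ia] if hasattr(ida, "iloc") else ida[ia],
                         "spot_id_b": idb.iloc[ib] if hasattr(idb, "iloc") else idb[ib],
                         "distance_um": d})
        pairs = pd.DataFrame(rows, columns=["spot_id_a", "spot_id_b", "distance_um"])
        frac = len(pairs) / len(a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ColocResult(
        pairs=pairs,
        nn_distances_um=np.asarray(nn),
        fraction_colocalized=frac,
        radius_um=radius_um,
        n_a=len(a),
        n_b=len(b),
        compartment=compartment or "all",
    )


def nn_distance_histogram(result: ColocResult, bin_um: float = 0.05, max_um: float = 1.0) -> pd.DataFrame:
    """Binned nearest-neighbour distance histogram (50-nm bins)."""
    edges = np.arange(0.0, max_um + bin_um, bin_um)
    finite = result.nn_distances_um[np.isfinite(result.nn_distances_um)]
    hist, _ = np.histogram(finite, bins=edges)
    return pd.DataFrame({"bin_left_um": edges[:-1], "count": hist})


def count_cells(
    classified_spots: pd.DataFrame,
    *,
    max_alleles: int = 4,
) -> list[CellCounts]:
    """Per-cell counts of transcription sites and single mRNAs."""
    counts = []
    spots = classified_spots[classified_spots["cell_id"] >= 0]
    for cid, grp in spots.groupby("cell_id", sort=True):
        n_ts = int(((grp["kind"] == "transcription_site")).sum())
        n_nuc = int(((grp["compartment"] == "nucleus") & (grp["kind"] == "single_mrna")).sum())
        n_cyt = int(((grp["compartment"] == "cytoplasm") & (grp["kind"] == "single_mrna")).sum())
        counts.append(
            CellCounts(cell_id=int(cid), n_ts=n_ts, n_nuclear_mrna=n_nuc,
                       n_cytoplasmic_mrna=n_cyt, max_alleles=max_alleles)
        )
    return counts


def probe_correlation(counts_a, counts_b) -> CorrelationResult:
    """Pearson correlation of paired per-cell counts from two probes."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("count vectors must be paired (equal length)")
    if len(a) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in counts")
    r, _ = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), n=len(a))
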