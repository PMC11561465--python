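"""Detection and characterization of Ki67 clusters (KCs).

A KC is a group of at least 4 proliferating (Ki67+) cells in direct contact —
the transient neurogenic focus that forms when a striatal astrocyte activates
after injury. Cells are staged from their marker flags, never stored:

* TAP   (transit-amplifying progenitor)  Ki67+ DCX-
* prNB  (proliferating neuroblast)       Ki67+ DCX+
* pmNB  (postmitotic neuroblast)         Ki67- DCX+

"Direct contact" is operationalized as a Euclidean ball of configurable
radius (default 12 um, about one soma diameter): Ki67+ cells within that
radius of each other are linked, and connected components of size >= 4 are
KCs. Smaller components (singles / pairs / trios) are returned separately —
they are the putative just-activated astrocyte progeny analyzed against KC
positions elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import cKDTree

DEFAULT_CONTACT_RADIUS = 12.0  # um, ~ soma diameter

KC_TYPES = ["TAPs-only", "TAPs+prNBs_Low", "TAPs+prNBs_Med", "TAPs+prNBs_High", "prNBs-only"]

CELL_COLUMNS = [
    "specimen_id", "cell_id", "x_um", "y_um", "z_um",
    "ki67", "dcx", "sox9", "brdu", "reporter", "kc_id",
]


def cell_stage(ki67, dcx) -> np.ndarray:
    """Derive cell stage from marker flags (vectorized)."""
    ki67 = np.asarray(ki67, bool)
    dcx = np.asarray(dcx, bool)
    out = np.where(ki67 & ~dcx, "TAP", np.where(ki67 & dcx, "prNB", np.where(dcx, "pmNB", "other")))
    return out


def detect_kcs(
    cells: pd.DataFrame,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Cluster Ki67+ cells into KCs by transitive direct contact.

    Parameters
    ----------
    cells
        Cell table with columns ``x_um, y_um, z_um, ki67, dcx`` (extra
        columns pass through untouched).
    contact_radius
        Maximum center-to-center distance (um) counting as direct contact.

    Returns
    -------
    assignment
        Per-row KC id (Int64; <NA> for Ki67- cells and for members of
        sub-threshold components), indexed like ``cells``.
    kcs
        One row per component of size >= 4: kc_id, n_tap, n_prnb, size,
        prnb_fraction, kc_type, centroid coordinates, member row labels.
    small_groups
        Components of size 1-3 (group_id, size, centroid, member rows) —
        the singles / pairs / trios.

    Notes
    -----
    KC ids are assigned by lexicographic order of component centroids, so the
    partition and the ids are invariant to input row order. Empty input gives
    empty tables.
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be positive")
    for col in ("x_um", "y_um", "z_um", "ki67", "dcx"):
        if col not in cells.columns:
            raise ValueError(f"cell table missing required column {col!r}")
    xyz_all = cells[["x_um", "y_um", "z_um"]].to_numpy(float)
    if len(cells) and not np.all(np.isfinite(xyz_all)):
        raise ValueError("non-finite cell coordinates")

    assignment = pd.Series(pd.array([pd.NA] * len(cells), dtype="Int64"), index=cells.index, name="kc_id")
    empty_kcs = pd.DataFrame(
        columns=["kc_id", "n_tap", "n_prnb", "size", "prnb_fraction", "kc_type", "x_um", "y_um", "z_um", "members"]
    )
    empty_small = pd.DataFrame(columns=["group_id", "size", "x_um", "y_um", "z_um", "members"])
    prolif = cells["ki67"].astype(bool).to_numpy()
    if prolif.sum() == 0:
        return assignment, empty_kcs, empty_small

    idx = np.flatnonzero(prolif)
    xyz = xyz_all[idx]
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=contact_radius, output_type="ndarray")
    n = len(idx)
    if len(pairs):
        adj = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    dcx = cells["dcx"].astype(bool).to_numpy()[idx]
    kc_rows, small_rows = [], []
    for comp in range(n_comp):
        members = idx[labels == comp]
        cen = xyz_all[members].mean(axis=0)
        rec = {
            "size": len(members),
            "x_um": cen[0], "y_um": cen[1], "z_um": cen[2],
            "members": cells.index[members].tolist(),
            "_mask": labels == comp,
        }
        (kc_rows if len(members) >= 4 else small_rows).append(rec)

    # order-invariant ids: sort by centroid
    def _sorted(rows):
        return sorted(rows, key=lambda r: (r["x_um"], r["y_um"], r["z_um"]))

    kc_out = []
    for kc_id, rec in enumerate(_sorted(kc_rows)):
        mask = rec.pop("_mask")
        n_prnb = int(dcx[mask].sum())
        size = rec["size"]
        n_tap = size - n_prnb
        assignment.loc[cells.index[idx[mask]]] = kc_id
        kc_out.append(
            {
                "kc_id": kc_id,
                "n_tap": n_tap,
                "n_prnb": n_prnb,
                "size": size,
                "prnb_fraction": n_prnb / size,
                "kc_type": classify_kc(n_tap, n_prnb),
                **{k: rec[k] for k in ("x_um", "y_um", "z_um", "members")},
            }
        )
    small_out = [
        {"group_id": gid, **{k: rec[k] for k in ("size", "x_um", "y_um", "z_um", "members")}}
        for gid, rec in enumerate(_sorted(small_rows))
    ]
    kcs = pd.DataFrame(kc_out) if kc_out else empty_kcs
    small = pd.DataFrame(small_out) if small_out else empty_small
    return assignment, kcs, small


def classify_kc(n_tap: int, n_prnb: int) -> str:
    """Maturation type of a KC from its TAP / prNB counts.

    Pure compositions map to ``TAPs-only`` / ``prNBs-only``; mixed KCs are
    binned by prNB fraction into tertiles (0, 1/3], (1/3, 2/3], (2/3, 1) →
    Low / Med / High. Total function on any valid KC (size >= 4 when taken
    from detection; sizes >= 1 are tolerated for direct calls on counts,
    but negative counts or an empty KC are errors).
    """
    n_tap, n_prnb = int(n_tap), int(n_prnb)
    if n_tap < 0 or n_prnb < 0 or n_tap + n_prnb == 0:
        raise ValueError("invalid KC composition")
    if n_tap + n_prnb < 4:
        raise ValueError("a KC has at least 4 cells")
    f = n_prnb / (n_tap + n_prnb)
    if f == 0.0:
        return "TAPs-only"
    if f == 1.0:
        return "prNBs-only"
    if f <= 1.0 / 3.0:
        return "TAPs+prNBs_Low"
    if f <= 2.0 / 3.0:
        return "TAPs+prNBs_Med"
    return "TAPs+prNBs_High"


def labeling_index(kcs: pd.DataFrame, n_labeled_col: str = "n_labeled", size_col: str = "size") -> dict:
    """Per-specimen labeling index (LI) summary.

    LI = fraction of KCs containing at least one labeled cell. Also reports
    the fraction of labeled KCs that are fully labeled and a fixed-width
    (0.1) histogram of per-KC labeled-cell fractions among labeled KCs.
    With zero KCs the LI is undefined and flagged, not reported as 0.
    """
    if n_labeled_col not in kcs.columns:
        raise ValueError(f"label column {n_labeled_col!r} missing")
    n_kc = len(kcs)
    if n_kc == 0:
        return {"n_kc": 0, "li": np.nan, "defined": False,
                "fully_labeled_fraction": np.nan, "histogram": None}
    n_lab = kcs[n_labeled_col].to_numpy(float)
    size = kcs[size_col].to_numpy(float)
    labeled = n_lab >= 1
    li = labeled.mean()
    frac = n_lab[labeled] / size[labeled]
    fully = float((frac >= 1.0).mean()) if labeled.any() else np.nan
    edges = np.arange(0.0, 1.1, 0.1)
    hist, _ = np.histogram(frac, bins=edges) if labeled.any() else (np.zeros(10, int), edges)
    return {
        "n_kc": int(n_kc),
        "li": float(li),
        "defined": True,
        "n_labeled_kcs": int(labeled.sum()),
        "fully_labeled_fraction": fully,
        "histogram": pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}),
    }


def clonality_summary(cells: pd.DataFrame, kc_col: str = "kc_id", reporter_col: str = "reporter") -> dict:
    """Clonality of reporter expression within KCs (Confetti analysis).

    A KC is *labeled* if at least one member cell carries a reporter color.
    It is *single-color* if all its labeled cells share one color and no
    member is non-recombined (colorless); otherwise it is *mixed* — the
    definition that counts KCs containing unlabeled cells as mixed. The
    non-recombined fraction is computed over all cells of labeled KCs.
    """
    if reporter_col not in cells.columns:
        raise ValueError(f"reporter column {reporter_col!r} missing")
    df = cells[cells[kc_col].notna()]
    rep = df[reporter_col].fillna("none").astype(str)
    colored = rep != "none"

    labeled_ids = df.loc[colored, kc_col].unique()
    n_single = 0
    per_color: dict[str, int] = {}
    n_cells_labeled_kcs = 0
    n_nonrecombined = 0
    for kc in labeled_ids:
        sub = rep[df[kc_col] == kc]
        colors = sub[sub != "none"].unique()
        n_cells_labeled_kcs += len(sub)
        n_none = int((sub == "none").sum())
        n_nonrecombined += n_none
        if len(colors) == 1 and n_none == 0:
            n_single += 1
            per_color[colors[0]] = per_color.get(colors[0], 0) + 1
    n_labeled = len(labeled_ids)
    return {
        "n_labeled_kcs": int(n_labeled),
        "n_single_color": int(n_single),
        "n_mixed": int(n_labeled - n_single),
        "per_color_counts": per_color,
        "single_color_fraction": n_single / n_labeled if n_labeled else np.nan,
        "n_cells_in_labeled_kcs": int(n_cells_labeled_kcs),
        "n_nonrecombined_cells": int(n_nonrecombined),
        "nonrecombined_fraction": (
            n_nonrecombined / n_cells_labeled_kcs if n_cells_labeled_kcs else np.nan
        ),
    }


def expected_same_color(
    n_kc: int,
    color_probs,
    n_sim: int = 999,
    seed: int | np.random.Generator | None = None,
    observed=None,
) -> dict:
    """Expected per-color KC counts under independent recombination.

    If each KC's founder lineage draws color c with probability p_c
    (multinomial; remainder unlabeled), the expected count of color-c KCs is
    n_kc * p_c. A Monte-Carlo ensemble of ``n_sim`` multinomial draws gives a
    95% interval per color and, when ``observed`` counts are supplied, a
    two-sided rank p value for the total same-color KC count.
    """
    if n_sim < 99:
        raise ValueError("n_sim < 99 gives too coarse a Monte-Carlo resolution; refused")
    p = np.asarray(color_probs, float)
    if np.any((p < 0) | (p > 1)) or p.sum() > 1 + 1e-12:
        raise ValueError("color probabilities must be in [0,1] and sum to <= 1")
    if n_kc < 0:
        raise ValueError("n_kc must be >= 0")
    rng = np.random.default_rng(seed)
    probs_full = np.append(p, 1.0 - p.sum())
    draws = rng.multinomial(n_kc, probs_full, size=n_sim)[:, : len(p)]
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    out = {
        "expected": n_kc * p,
        "mc_interval_low": lo,
        "mc_interval_high": hi,
        "n_sim": n_sim,
    }
    if observed is not None:
        obs = np.asarray(observed, float)
        if obs.shape != p.shape:
            raise ValueError("observed counts must align with color_probs")
        tot_null = draws.sum(axis=1)
        tot_obs = obs.sum()
        p_hi = (1 + np.sum(tot_null >= tot_obs)) / (n_sim + 1)
        p_lo = (1 + np.sum(tot_null <= tot_obs)) / (n_sim + 1)
        out["p_value"] = float(min(1.0, 2.0 * min(p_hi, p_lo)))
        out["observed"] = obs
    return out
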