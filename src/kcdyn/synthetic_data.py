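"""Synthetic specimens with the statistical structure of injury-induced
striatal neurogenesis.

The study's 3D microscopy reconstructions are not publicly deposited, so this
module generates cell tables, Ki67-cluster (KC) populations, point patterns,
and labeling experiments whose statistics mirror the printed summaries:

* KC counts per specimen around 288 (observed range 55-586);
* KC sizes 4-38 cells with mean 11.8 and SD 7.6, about half of KCs being pure
  (TAPs-only or prNBs-only) and the rest mixed;
* steady-state turnover at 9.4 %/day (lifetime 10.6 days), giving a uniform
  steady-state KC age distribution;
* saturating BrdU pulse labeling ~74 % of the cells of every pre-existing KC;
* Confetti recombination fractions of 2.4 / 1.2 / 1.7 % per color and a YFP
  lineage-labeling plateau of ~36 %.

All generators are pure functions of (parameters, seed).

Size-law calibration
--------------------
KC sizes are drawn from an integer-rounded truncated normal on [4, 38]. The
truncated law's (loc, scale) are *calibrated* so that the truncated
distribution has the target mean exactly; no truncated normal on [4, 38] can
have mean 11.8 and SD as large as 7.6 simultaneously (the real size data are
right-skewed), so the scale is chosen to bring the SD as close as possible
(about 7.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import kc_analysis
from .kc_analysis import classify_kc, detect_kcs
from .regions import BoxRegion, RegionMask
from .spatial_stats import PointPattern3D
from .turnover_model import RenewalParams


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class CompositionParams:
    """Parameters of the KC composition generator.

    ``type_weights`` are the probabilities of (TAPs-only, mixed, prNBs-only)
    KCs; the default splits the printed "about half pure" evenly between the
    two pure types. ``pmnb_logit`` are (intercept, coef on prNB fraction,
    coef on size) of the logistic association law for postmitotic-neuroblast
    attachment, rising with maturity. ``dormant_prob`` is the probability
    that at least one dormant (Ki67- DCX-) astrocyte stays clustered with
    the KC; rarely there are two.
    """

    mean_size: float = 11.8
    sd_size: float = 7.6
    min_size: int = 4
    max_size: int = 38
    type_weights: tuple[float, float, float] = (0.25, 0.50, 0.25)
    pmnb_logit: tuple[float, float, float] = (-2.2, 2.5, 0.08)
    dormant_prob: float = 0.75
    dormant_two_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.min_size < 4:
            raise ValueError("min KC size must be >= 4 (the KC definition)")
        if not self.min_size <= self.max_size:
            raise ValueError("need min_size <= max_size")
        if self.sd_size <= 0:
            raise ValueError("size SD must be positive")
        w = np.asarray(self.type_weights, float)
        if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("type mixture weights must be 3 nonnegatives summing to 1")
        if not 0 <= self.dormant_two_prob <= self.dormant_prob <= 1:
            raise ValueError("need 0 <= dormant_two_prob <= dormant_prob <= 1")


@dataclass(frozen=True)
class LabelDesign:
    """One labeling experiment.

    ``modality``:

    * ``brdu-pulse`` — saturating thymidine-analog pulse; every cell of a KC
      that existed at pulse time is labeled independently with
      ``cell_label_prob``; ``chase`` days elapse before sacrifice.
    * ``tam-confetti`` — tamoxifen-induced stochastic multicolor reporter;
      each lineage initiating after tamoxifen draws color c with probability
      ``color_probs[c]`` (remainder unlabeled); ``interval`` days from
      tamoxifen to sacrifice.
    * ``tam-yfp`` — single-color heritable reporter; lineage labeled with
      ``lineage_label_prob``.
    """

    modality: str = "brdu-pulse"
    cell_label_prob: float = 0.74
    lineage_label_prob: float = 0.361
    color_probs: dict = field(default_factory=lambda: {"rfp": 0.024, "mcfp": 0.012, "cyfp": 0.017})
    chase: float = 4.0
    interval: float = 14.0

    def __post_init__(self) -> None:
        if self.modality not in ("brdu-pulse", "tam-confetti", "tam-yfp"):
            raise ValueError(f"unknown modality {self.modality!r}")
        for p in (self.cell_label_prob, self.lineage_label_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        cp = np.asarray(list(self.color_probs.values()), float)
        if np.any((cp < 0) | (cp > 1)) or cp.sum() > 1 + 1e-12:
            raise ValueError("color probabilities must be in [0,1] and sum to <= 1")
        if self.chase < 0:
            raise ValueError("chase must be >= 0")
        if self.interval < 0:
            raise ValueError("administration-to-sacrifice interval must be >= 0")


# ---------------------------------------------------------------------------
# size law

@lru_cache(maxsize=32)
def _calibrated_size_law(mean: float, sd: float, lo: int, hi: int):
    """(a, b, loc, scale) of the truncated normal on [lo-1/2, hi+1/2] whose
    truncated mean equals ``mean`` and whose SD is as close as possible to
    ``sd``. Monotonicity of the truncated mean in loc makes the inner solve a
    bracketed root-find; the outer search scans the scale."""
    lo_c, hi_c = lo - 0.5, hi + 0.5

    def trunc(loc, scale):
        a, b = (lo_c - loc) / scale, (hi_c - loc) / scale
        return stats.truncnorm(a, b, loc=loc, scale=scale)

    def loc_for_mean(scale):
        f = lambda loc: trunc(loc, scale).mean() - mean
        lo_b, hi_b = lo_c - 200 * scale, hi_c
        if f(lo_b) > 0 or f(hi_b) < 0:
            return None
        return optimize.brentq(f, lo_b, hi_b, xtol=1e-10)

    best = None
    for scale in np.geomspace(0.3 * sd, 6 * sd, 60):
        loc = loc_for_mean(scale)
        if loc is None:
            continue
        err = abs(trunc(loc, scale).std() - sd)
        if best is None or err < best[0]:
            best = (err, loc, scale)
    if best is None:
        raise ValueError(f"cannot calibrate a truncated normal to mean {mean} on [{lo}, {hi}]")
    _, loc, scale = best
    a, b = (lo_c - loc) / scale, (hi_c - loc) / scale
    return a, b, loc, scale


def _draw_sizes(n: int, params: CompositionParams, rng: np.random.Generator) -> np.ndarray:
    a, b, loc, scale = _calibrated_size_law(
        params.mean_size, params.sd_size, params.min_size, params.max_size
    )
    raw = stats.truncnorm(a, b, loc=loc, scale=scale).rvs(n, random_state=rng)
    return np.clip(np.round(raw).astype(int), params.min_size, params.max_size)


# ---------------------------------------------------------------------------
# point patterns

def gen_point_pattern(
    region: RegionMask,
    n: int | None,
    process: str = "csr",
    process_params: dict | None = None,
    seed: int | np.random.Generator | None = None,
) -> PointPattern3D:
    """Generate a 3D point pattern in a region.

    ``csr`` draws exactly ``n`` uniform points — the null engine behind all
    envelope tests. ``clustered`` is a Thomas process (Poisson parents,
    isotropic-Gaussian offspring; the count is Poisson unless ``n`` forces
    it); ``inhibited`` is hard-core dart throwing with minimum separation
    ``hard_core``. The latter two are test fixtures for power checks and for
    merge-safe specimen construction.
    """
    rng = np.random.default_rng(seed)
    pp = process_params or {}
    if process == "csr":
        if n is None or n < 0:
            raise ValueError("csr needs n >= 0")
        return PointPattern3D(region.sample_uniform(n, rng).reshape(-1, 3), region)

    if process == "clustered":
        sigma = float(pp.get("sigma", 30.0))
        if "n_parents" in pp:
            n_par = int(pp["n_parents"])
        else:
            parent_intensity = pp.get("parent_intensity")
            if parent_intensity is None:
                raise ValueError("clustered process needs n_parents or parent_intensity")
            n_par = rng.poisson(float(parent_intensity) * region.volume)
        n_par = max(n_par, 1)
        parents = region.sample_uniform(n_par, rng)
        if n is not None:
            n_off = int(n)
        else:
            mu = float(pp.get("mean_offspring", 10.0))
            n_off = int(rng.poisson(mu * n_par))
        assign = rng.integers(0, n_par, size=n_off)
        pts = np.empty((n_off, 3))
        for i in range(n_off):
            for _ in range(1000):
                cand = parents[assign[i]] + rng.normal(0.0, sigma, size=3)
                if region.contains(cand[None, :])[0]:
                    pts[i] = cand
                    break
            else:  # pathological sigma; fall back to the parent location
                pts[i] = parents[assign[i]]
        return PointPattern3D(pts, region)

    if process == "inhibited":
        if n is None or n < 0:
            raise ValueError("inhibited needs n >= 0")
        hc = float(pp.get("hard_core", 0.0))
        if hc <= 0:
            raise ValueError("inhibited process needs a positive hard_core radius")
        sphere_vol = 4.0 / 3.0 * np.pi * (hc / 2.0) ** 3
        if n * sphere_vol > region.volume:
            raise ValueError(
                f"infeasible packing: {n} hard-core spheres of diameter {hc} um "
                f"exceed the region volume"
            )
        pts = np.empty((n, 3))
        placed = 0
        attempts = 0
        max_attempts = 2000 * max(n, 1)
        while placed < n:
            if attempts > max_attempts:
                raise RuntimeError(
                    "hard-core placement did not converge; packing too dense"
                )
            cand = region.sample_uniform(1, rng)[0]
            attempts += 1
            if placed == 0 or np.all(np.linalg.norm(pts[:placed] - cand, axis=1) >= hc):
                pts[placed] = cand
                placed += 1
        return PointPattern3D(pts, region)

    raise ValueError(f"unknown process {process!r}")


# ---------------------------------------------------------------------------
# KC composition

def gen_kc_composition(
    n_kc: int,
    params: CompositionParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a KC population: sizes, TAP/prNB composition, pmNB association,
    dormant astrocytes.

    Sizes follow the calibrated integer-rounded truncated normal; each KC's
    type (TAPs-only / mixed / prNBs-only) is multinomial with
    ``params.type_weights``; mixed KCs draw their prNB fraction uniformly,
    keeping at least one cell of each stage. The pmNB-association flag is
    Bernoulli with logistic probability in (prNB fraction, size).
    """
    if n_kc < 0:
        raise ValueError("n_kc must be >= 0")
    params = params or CompositionParams()
    rng = np.random.default_rng(seed)

    size = _draw_sizes(n_kc, params, rng)
    kind = rng.choice(3, size=n_kc, p=np.asarray(params.type_weights, float))
    frac = rng.random(n_kc)
    n_prnb = np.where(
        kind == 0, 0,
        np.where(kind == 2, size, np.clip(np.round(frac * size), 1, size - 1).astype(int)),
    )
    n_tap = size - n_prnb
    prnb_fraction = n_prnb / size

    b0, b1, b2 = params.pmnb_logit
    p_pmnb = 1.0 / (1.0 + np.exp(-(b0 + b1 * prnb_fraction + b2 * size)))
    pmnb = rng.random(n_kc) < p_pmnb

    u = rng.random(n_kc)
    dormant = np.where(u < params.dormant_two_prob, 2, np.where(u < params.dormant_prob, 1, 0))

    df = pd.DataFrame(
        {
            "kc_id": np.arange(n_kc),
            "n_tap": n_tap.astype(int),
            "n_prnb": n_prnb.astype(int),
            "size": size.astype(int),
            "prnb_fraction": prnb_fraction,
            "pmnb_assoc": pmnb,
            "n_dormant": dormant.astype(int),
        }
    )
    df["kc_type"] = [classify_kc(t, p) for t, p in zip(df["n_tap"], df["n_prnb"])]
    return df


# ---------------------------------------------------------------------------
# labeling experiments

def gen_labeled_population(
    renewal: RenewalParams,
    design: LabelDesign,
    comp: CompositionParams | None = None,
    n_kc: int = 288,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """KC population with steady-state ages and a labeling experiment applied.

    Ages are drawn from the steady-state age distribution of the renewal
    model (uniform on [0, tau) for the fixed-lifetime model; exponential
    otherwise, truncated at 5 tau). Maturation advances with age: the prNB
    fraction grows linearly from 0 to 1 over one lifetime, so young KCs are
    TAP-rich and old KCs prNB-rich.

    Label rules:

    * ``brdu-pulse``: a KC older than the chase existed at pulse time — each
      of its cells is labeled independently with ``cell_label_prob``; younger
      KCs (initiated during the chase) carry no label.
    * ``tam-confetti`` / ``tam-yfp``: a KC initiated after tamoxifen (age <
      interval) has its founding lineage labeled (with the color law /
      ``lineage_label_prob``); labels are heritable, so all member cells of a
      labeled KC are labeled.
    """
    comp = comp or CompositionParams()
    rng = np.random.default_rng(seed)
    df = gen_kc_composition(n_kc, comp, rng)

    if renewal.lifetime_model == "fixed":
        age = rng.uniform(0.0, renewal.tau, size=n_kc)
    else:
        age = np.minimum(rng.exponential(renewal.tau, size=n_kc), 5 * renewal.tau)
    df["age_days"] = age

    # maturation-age coupling: prNB fraction tracks age/tau
    frac = np.clip(age / renewal.tau, 0.0, 1.0)
    n_prnb = np.round(frac * df["size"]).astype(int)
    df["n_prnb"] = n_prnb
    df["n_tap"] = df["size"] - n_prnb
    df["prnb_fraction"] = df["n_prnb"] / df["size"]
    df["kc_type"] = [classify_kc(t, p) for t, p in zip(df["n_tap"], df["n_prnb"])]

    size = df["size"].to_numpy(int)
    if design.modality == "brdu-pulse":
        existed = age > design.chase
        n_labeled = np.where(existed, rng.binomial(size, design.cell_label_prob), 0)
        df["n_labeled"] = n_labeled
        df["labeled"] = n_labeled > 0
        df["reporter"] = "none"
    else:
        initiated_after_tam = age < design.interval
        if design.modality == "tam-yfp":
            lab = initiated_after_tam & (rng.random(n_kc) < design.lineage_label_prob)
            color = np.where(lab, "yfp", "none")
        else:
            colors = list(design.color_probs)
            probs = np.asarray([design.color_probs[c] for c in colors], float)
            full = np.append(probs, 1.0 - probs.sum())
            draw = rng.choice(len(colors) + 1, size=n_kc, p=full)
            color = np.asarray([*(colors), "none"], dtype=object)[draw]
            color = np.where(initiated_after_tam, color, "none")
            lab = color != "none"
        df["reporter"] = color
        df["labeled"] = lab
        df["n_labeled"] = np.where(lab, size, 0)
    return df


# ---------------------------------------------------------------------------
# whole specimens

# cubic lattice sites sorted by distance to the origin; spacing multiplies in
_LATTICE_RANGE = 5


@lru_cache(maxsize=1)
def _lattice_sites() -> np.ndarray:
    g = np.arange(-_LATTICE_RANGE, _LATTICE_RANGE + 1)
    sites = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T.astype(float)
    order = np.argsort(np.einsum("ij,ij->i", sites, sites), kind="stable")
    return sites[order]


@dataclass(frozen=True)
class SpecimenConfig:
    """Configuration of one synthetic specimen."""

    n_kc: int = 288
    region: RegionMask = field(default_factory=lambda: BoxRegion(hi=(2000.0, 2000.0, 2000.0)))
    composition: CompositionParams = field(default_factory=CompositionParams)
    renewal: RenewalParams = field(default_factory=RenewalParams)
    label_design: LabelDesign | None = None
    contact_radius: float = kc_analysis.DEFAULT_CONTACT_RADIUS
    lattice_factor: float = 0.7  # cell spacing as a fraction of contact radius
    jitter_factor: float = 0.1   # positional jitter as a fraction of spacing
    centroid_process: str = "inhibited"  # merge-safe default
    specimen_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kc < 0 or self.n_kc > 5000:
            raise ValueError("n_kc outside plausible bounds [0, 5000]")
        if not 0.3 <= self.lattice_factor <= 0.9:
            raise ValueError("lattice_factor must keep neighbors within contact")


@dataclass
class Specimen:
    """A generated specimen bundle."""

    cells: pd.DataFrame
    kcs: pd.DataFrame
    small_groups: pd.DataFrame
    pattern: PointPattern3D
    region: RegionMask
    config: SpecimenConfig
    metadata: dict


def _place_cluster(
    centroid: np.ndarray, n_cells: int, spacing: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Compact, contact-connected cell positions around a centroid.

    Takes the ``n_cells`` cubic-lattice sites nearest the origin (so face
    neighbors are ``spacing`` apart and the component is connected), applies
    a random rotation, and jitters each site by up to ``jitter`` per axis.
    """
    sites = _lattice_sites()[:n_cells] * spacing
    # random rotation (QR of a Gaussian matrix)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    pts = sites @ q.T
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    return centroid + pts


def max_cluster_radius(max_size: int, contact_radius: float, lattice_factor: float = 0.7,
                       jitter_factor: float = 0.1) -> float:
    """Radius of the ball that surely contains any generated KC's cells."""
    spacing = lattice_factor * contact_radius
    sites = _lattice_sites()[:max_size]
    r = float(np.linalg.norm(sites, axis=1).max()) * spacing
    return r + jitter_factor * spacing * np.sqrt(3.0)


def gen_specimen(config: SpecimenConfig | None = None) -> Specimen:
    """Compose the generators into one specimen: a KC table, its centroid
    point pattern, and a cell-level table that `detect_kcs` maps back onto
    the KC table.

    Centroids are placed with a hard-core exclusion distance large enough
    that distinct KCs can never touch (the default); with ``centroid_process
    = 'csr'`` merges are possible and are surfaced as a warning in the bundle
    metadata rather than an error.
    """
    config = config or SpecimenConfig()
    rng = np.random.default_rng(config.seed)

    if config.label_design is not None:
        kcs = gen_labeled_population(
            config.renewal, config.label_design, config.composition, config.n_kc, rng
        )
    else:
        kcs = gen_kc_composition(config.n_kc, config.composition, rng)
        kcs["age_days"] = rng.uniform(0.0, config.renewal.tau, size=config.n_kc)
        kcs["labeled"] = False
        kcs["n_labeled"] = 0
        kcs["reporter"] = "none"

    spacing = config.lattice_factor * config.contact_radius
    jitter = config.jitter_factor * spacing
    r_max = max_cluster_radius(
        config.composition.max_size + 3,  # headroom for pmNB / dormant attachments
        config.contact_radius, config.lattice_factor, config.jitter_factor,
    )
    hard_core = 2.0 * r_max + config.contact_radius * 1.05

    metadata: dict = {"seed": config.seed, "hard_core_um": hard_core, "warnings": []}
    if config.centroid_process == "inhibited":
        pattern = gen_point_pattern(
            config.region, config.n_kc, "inhibited", {"hard_core": hard_core}, rng
        )
    else:
        pattern = gen_point_pattern(config.region, config.n_kc, config.centroid_process, None, rng)
        if len(pattern) >= 2:
            from .spatial_stats import nn_distances

            d, _ = nn_distances(pattern)
            if np.any(d < hard_core):
                metadata["warnings"].append(
                    f"{int((d < hard_core).sum())} KC centroid(s) closer than the merge-safe "
                    f"distance {hard_core:.1f} um; detected KCs may merge"
                )

    rows = []
    cell_id = 0
    for i, kc in kcs.iterrows():
        centroid = pattern.points[i]
        n_extra = int(kc["pmnb_assoc"]) + int(kc["n_dormant"])
        pos = _place_cluster(centroid, int(kc["size"]) + n_extra, spacing, jitter, rng)
        stages = (
            ["TAP"] * int(kc["n_tap"]) + ["prNB"] * int(kc["n_prnb"])
            + ["pmNB"] * int(kc["pmnb_assoc"]) + ["dormant"] * int(kc["n_dormant"])
        )
        labeled_cells = set(rng.choice(int(kc["size"]), size=int(kc["n_labeled"]), replace=False))
        for j, (p, stage) in enumerate(zip(pos, stages)):
            rows.append(
                {
                    "specimen_id": config.specimen_id,
                    "cell_id": cell_id,
                    "x_um": p[0], "y_um": p[1], "z_um": p[2],
                    "ki67": stage in ("TAP", "prNB"),
                    "dcx": stage in ("prNB", "pmNB"),
                    "sox9": "high" if stage == "dormant" else "neg",
                    "brdu": (
                        j in labeled_cells
                        if (config.label_design and config.label_design.modality == "brdu-pulse")
                        else False
                    ),
                    "reporter": (
                        kc["reporter"]
                        if (j < int(kc["size"]) and j in labeled_cells
                            and config.label_design
                            and config.label_design.modality != "brdu-pulse")
                        else "none"
                    ),
                    "gen_kc_id": i,
                }
            )
            cell_id += 1
    cells = pd.DataFrame(
        rows,
        columns=["specimen_id", "cell_id", "x_um", "y_um", "z_um", "ki67", "dcx",
                 "sox9", "brdu", "reporter", "gen_kc_id"],
    )

    assignment, detected, small = detect_kcs(cells, config.contact_radius)
    cells["kc_id"] = assignment
    if len(detected) != config.n_kc:
        metadata["warnings"].append(
            f"detected {len(detected)} KCs from {config.n_kc} generated (merge or split)"
        )
    # carry generator metadata onto the detected table where the mapping is clean
    if len(detected) == config.n_kc and len(detected):
        gen_for_detected = (
            cells.loc[cells["kc_id"].notna()]
            .groupby("kc_id")["gen_kc_id"]
            .agg(lambda s: s.iloc[0])
        )
        meta_cols = ["age_days", "labeled", "n_labeled", "reporter", "pmnb_assoc", "n_dormant"]
        detected = detected.merge(
            kcs.loc[gen_for_detected.to_numpy(), meta_cols].reset_index(drop=True),
            left_index=True, right_index=True,
        )
    centroid_pattern = PointPattern3D(pattern.points, config.region)
    return Specimen(
        cells=cells,
        kcs=detected,
        small_groups=small,
        pattern=centroid_pattern,
        region=config.region,
        config=config,
        metadata=metadata,
    )
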