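"""Weighted composite indices, the Getis-Ord Gi* statistic, and priority areas.

For each of the three metrics (SE, SR, SN) the three biological layers are
min-max normalized and combined with expert weights — 0.35 for non-threatened
mollusks (broad coverage, lower conservation priority), 0.45 for threatened
mollusks (sparse but high conservation value), 0.20 for biogenic habitats
(enabling conditions rather than targets). The composite field is then
screened for local clustering with the Getis-Ord Gi* statistic, computed
from scratch on the lattice:

    z_i = [ Σ_j w_ij x_j − X̄ W_i ] / [ S · sqrt( (n Σ_j w_ij² − W_i²) / (n−1) ) ]

with binary contiguity weights (w_ii = 1; queen by default), W_i = Σ_j w_ij,
and X̄, S the global mean and *population* standard deviation over all n
cells (empty ocean cells included: hotspot extent is reported as a percent
of the whole region). Z-scores are binned into 90/95/99% confidence tiers
via the two-tailed normal quantiles 1.645 / 1.960 / 2.576, and the priority
conservation area is the union of the three metrics' 99% hotspot cells,
labeled into contiguous sites by 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec

DEFAULT_WEIGHTS = {"ALL": 0.35, "TSP": 0.45, "CSM": 0.20}
DEFAULT_THRESHOLDS = (1.645, 1.960, 2.576)  # 90 / 95 / 99% two-tailed

TIERS = ("cold99", "cold95", "cold90", "not_significant", "hot90", "hot95", "hot99")
HOT_TIERS = ("hot90", "hot95", "hot99")

_KERNELS = {
    "queen": np.ones((3, 3)),
    "rook": np.array([[0.0, 1, 0], [1, 1, 1], [0, 1, 0]]),
}


def normalize_layer(values: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant layer maps to all zeros."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty layer")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def composite(
    metric: str,
    layers: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Weighted sum of the three normalized per-cell layer vectors."""
    weights = weights or DEFAULT_WEIGHTS
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError(f"layer weights must sum to 1, got {sum(weights.values())}")
    out = None
    for layer, w in weights.items():
        v = np.asarray(layers[layer], dtype=float)
        out = w * v if out is None else out + w * v
    return out


@dataclass
class GiStarResult:
    """Per-cell Gi* Z-scores and hot/cold tier labels for one composite index."""

    metric: str
    z: np.ndarray
    tier: np.ndarray  # strings from TIERS
    scheme: str
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def tier_counts(self) -> dict[str, int]:
        return {t: int((self.tier == t).sum()) for t in TIERS}

    def hot_cells(self, tier: str = "hot99") -> np.ndarray:
        """Flat cell ids at or above the given hot tier."""
        order = {t: i for i, t in enumerate(TIERS)}
        return np.flatnonzero(
            np.vectorize(order.get)(self.tier) >= order[tier]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": np.arange(self.z.size), "z": self.z, "tier": self.tier}
        )


def gi_star(
    values: np.ndarray | pd.Series,
    spec: GridSpec,
    scheme: str = "queen",
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    row_standardize: bool = False,
    background: str = "all",
    metric: str = "",
) -> GiStarResult:
    """Getis-Ord Gi* over the lattice, vectorized with a contiguity convolution.

    ``values`` is the flat per-cell vector (row-major, south-west origin).
    Binary weights w_ij = 1 for j in the focal cell's contiguity set plus
    itself; ``row_standardize`` divides each cell's weights by its W_i.
    A zero-variance field yields z = 0 everywhere (flagged not significant).

    ``background`` selects the analysis support: ``"all"`` runs the formula
    over every lattice cell; ``"occupied"`` restricts the statistic to cells
    with a positive value — the neighbor sets, n, X̄ and S then cover only
    those cells, which mirrors the common GIS workflow where only cells with
    data become polygons (and keeps the vast empty ocean from shrinking the
    global variance). Non-support cells get z = 0 / not significant.
    """
    if scheme not in _KERNELS:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    if background not in ("all", "occupied"):
        raise ValueError(f"unknown background rule {background!r}")
    x = np.asarray(values, dtype=float).reshape(spec.n_rows, spec.n_cols)
    n_total = x.size
    if n_total < 2:
        raise ValueError("Gi* needs at least two cells")
    kernel = _KERNELS[scheme]

    if background == "occupied":
        support = x > 0
        n = int(support.sum())
        field = np.where(support, x, 0.0)
        in_graph = support.astype(float)
    else:
        support = np.ones_like(x, dtype=bool)
        n = n_total
        field = x
        in_graph = np.ones_like(x)

    if n < 2:
        z = np.zeros(n_total)
        tier = classify_tiers(z, thresholds)
        return GiStarResult(metric=metric, z=z, tier=tier, scheme=scheme, thresholds=thresholds)

    local_sum = ndimage.convolve(field, kernel, mode="constant", cval=0.0)
    k_i = ndimage.convolve(in_graph, kernel, mode="constant", cval=0.0)

    vals = x[support]
    xbar = vals.mean()
    s = vals.std()  # population standard deviation
    if s == 0:
        z = np.zeros(n_total)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            if row_standardize:
                lag = np.where(k_i > 0, local_sum / k_i, 0.0)
                w_sum = np.ones_like(x)
                w_sq = np.where(k_i > 0, 1.0 / k_i, 0.0)
            else:
                lag = local_sum
                w_sum = k_i
                w_sq = k_i  # binary weights: Σ w² = Σ w
            denom = s * np.sqrt(np.maximum(n * w_sq - w_sum**2, 0.0) / (n - 1))
            z = np.where(support & (denom > 0), (lag - xbar * w_sum) / np.where(denom > 0, denom, 1.0), 0.0).ravel()
    tier = classify_tiers(z, thresholds)
    return GiStarResult(metric=metric, z=z, tier=tier, scheme=scheme, thresholds=thresholds)


def classify_tiers(
    z: np.ndarray, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Bin Z-scores into confidence tiers.

    hot99 for z ≥ 2.576, hot95 for 1.960 ≤ z < 2.576, hot90 for
    1.645 ≤ z < 1.960, mirrored for cold tiers, else not significant.
    """
    t90, t95, t99 = thresholds
    if not t90 < t95 < t99:
        raise ValueError("tier thresholds must be strictly increasing")
    z = np.asarray(z, dtype=float)
    tier = np.full(z.shape, "not_significant", dtype=object)
    tier[z >= t90] = "hot90"
    tier[z >= t95] = "hot95"
    tier[z >= t99] = "hot99"
    tier[z <= -t90] = "cold90"
    tier[z <= -t95] = "cold95"
    tier[z <= -t99] = "cold99"
    return tier.astype(str)


@dataclass
class PriorityMask:
    """Union of the three metrics' 99%-confidence hotspot cells.

    ``provenance`` maps each mask cell to the metrics whose hot99 set
    contributed it; ``sites`` labels 8-connected components (0 = outside),
    numbered 1..k in decreasing cell-count order.
    """

    mask: np.ndarray  # flat boolean, length n_cells
    provenance: dict[int, tuple[str, ...]] = field(default_factory=dict)
    sites: np.ndarray = None  # flat int labels

    @property
    def cells(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def n_sites(self) -> int:
        return 0 if self.sites is None else int(self.sites.max())


def composite_hotspots(
    layers: dict[str, pd.DataFrame],
    spec: GridSpec,
    weights: dict[str, float] | None = None,
    scheme: str = "queen",
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    background: str = "occupied",
    metrics: tuple[str, ...] = ("SE", "SR", "SN"),
) -> tuple[list[GiStarResult], "PriorityMask"]:
    """The study's hotspot screen: normalize, weight, Gi*, union of hot99.

    ``layers`` maps ALL/TSP/CSM to their per-cell metric tables. Returns the
    per-metric Gi* results and the priority mask.
    """
    weights = weights or DEFAULT_WEIGHTS
    results = []
    for metric in metrics:
        normalized = {name: normalize_layer(layers[name][metric]) for name in weights}
        comp = composite(metric, normalized, weights)
        results.append(
            gi_star(
                comp,
                spec,
                scheme=scheme,
                thresholds=thresholds,
                background=background,
                metric=metric,
            )
        )
    return results, priority_areas(results, spec)


def priority_areas(results: list[GiStarResult], spec: GridSpec) -> PriorityMask:
    """Union the hot99 cells of the three metric analyses into a priority mask."""
    sizes = {r.z.size for r in results}
    if sizes != {spec.n_cells}:
        raise ValueError("all Gi* results must live on the analysis lattice")
    mask = np.zeros(spec.n_cells, dtype=bool)
    provenance: dict[int, list[str]] = {}
    for r in results:
        for c in np.flatnonzero(r.tier == "hot99"):
            mask[c] = True
            provenance.setdefault(int(c), []).append(r.metric)
    labels, n_lab = ndimage.label(
        mask.reshape(spec.n_rows, spec.n_cols), structure=np.ones((3, 3))
    )
    # relabel components by decreasing size
    if n_lab:
        sizes_ = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
        order = np.argsort(-sizes_, kind="stable") + 1
        remap = np.zeros(n_lab + 1, dtype=int)
        remap[order] = np.arange(1, n_lab + 1)
        labels = remap[labels]
    return PriorityMask(
        mask=mask,
        provenance={c: tuple(m) for c, m in provenance.items()},
        sites=labels.ravel(),
    )


def summarize_priority(
    mask: PriorityMask,
    occ_all: pd.DataFrame,
    occ_threatened: pd.DataFrame,
    habitats: pd.DataFrame,
    spec: GridSpec,
) -> dict:
    """Record/species/habitat content of the priority mask.

    All occurrence tables must carry cell assignments (``cell_id``). Returns
    counts, species fractions, and the fraction of mask cells where all
    three biogenic habitats co-occur.
    """
    cells = set(int(c) for c in mask.cells)

    def in_mask(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["cell_id"].isin(cells)] if len(df) else df

    occ_in = in_mask(occ_all)
    thr_in = in_mask(occ_threatened)
    hab_in = in_mask(habitats)
    n_species = occ_all["species"].nunique() if len(occ_all) else 0
    n_thr_species = occ_threatened["species"].nunique() if len(occ_threatened) else 0
    co3 = 0
    if len(hab_in) and cells:
        types_per_cell = hab_in.groupby("cell_id")["habitat"].nunique()
        co3 = int((types_per_cell >= 3).sum())
    return {
        "n_priority_cells": len(cells),
        "n_sites": mask.n_sites,
        "records_in_mask": int(len(occ_in)),
        "threatened_records_in_mask": int(len(thr_in)),
        "habitat_records_in_mask": int(len(hab_in)),
        "species_in_mask": int(occ_in["species"].nunique()) if len(occ_in) else 0,
        "species_fraction": (occ_in["species"].nunique() / n_species) if n_species else 0.0,
        "threatened_species_in_mask": int(thr_in["species"].nunique()) if len(thr_in) else 0,
        "threatened_species_fraction": (
            thr_in["species"].nunique() / n_thr_species if n_thr_species else 0.0
        ),
        "all_three_habitats_fraction": (co3 / len(cells)) if cells else 0.0,
    }
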