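"""Per-cell diversity metrics and cross-layer Pearson correlations.

Three metrics per grid cell and biological layer:

* SE — sampling effort, the raw occurrence-record count;
* SR — species richness, the number of distinct species (or habitat types,
  for the biogenic-habitat layer);
* SN — the Shannon-Wiener index, −Σᵢ pᵢ ln pᵢ in nats, with pᵢ the share of
  the cell's records belonging to species i. Record counts per species stand
  in for abundance, since the inputs are presence records.

SN is 0 for cells with ≤ 1 species and bounded above by ln(SR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec, assign_cells

LAYERS = ("ALL", "TSP", "CSM")
METRICS = ("SE", "SR", "SN")


def attach_cells(records: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Return a copy of ``records`` with a flat ``cell_id`` column.

    Out-of-bounds rows (cell_id −1) are dropped.
    """
    out = records.copy()
    out["cell_id"] = assign_cells(
        out["lat"].to_numpy(dtype=float), out["lon"].to_numpy(dtype=float), spec
    )
    return out[out["cell_id"] >= 0].reset_index(drop=True)


def shannon_index(counts: np.ndarray) -> float:
    """Shannon-Wiener entropy (nats) of one cell's per-species record counts."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def layer_metrics(records: pd.DataFrame, spec: GridSpec, key: str = "species") -> pd.DataFrame:
    """SE/SR/SN per grid cell for one biological layer.

    ``key`` is the grouping column: ``species`` for the mollusk layers and
    ``habitat`` for the biogenic-habitat layer. Every one of the lattice's
    cells appears in the output; cells with no records carry zeros and
    ``empty=True``.
    """
    if "cell_id" not in records.columns:
        records = attach_cells(records, spec)
    out = pd.DataFrame(
        {"SE": 0, "SR": 0, "SN": 0.0, "empty": True},
        index=pd.RangeIndex(spec.n_cells, name="cell_id"),
    )
    if len(records):
        counts = records.groupby(["cell_id", key], observed=True).size()
        se = counts.groupby(level="cell_id").sum()
        sr = counts.groupby(level="cell_id").size()
        sn = counts.groupby(level="cell_id").agg(lambda c: shannon_index(c.to_numpy()))
        out.loc[se.index, "SE"] = se
        out.loc[sr.index, "SR"] = sr
        out.loc[sn.index, "SN"] = sn
        out.loc[se.index, "empty"] = False
    out["SE"] = out["SE"].astype(int)
    out["SR"] = out["SR"].astype(int)
    return out


def occupancy_fraction(layer: pd.DataFrame, spec: GridSpec) -> float:
    """Fraction of the lattice's cells containing at least one record."""
    return float((layer["SE"] > 0).sum() / spec.n_cells)


@dataclass
class CorrelationMatrix:
    """9×9 Pearson correlations across the three layers' three metrics."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  # cells in the support of each pair
    support: str  # "union_nonzero" or "all_cells"


def correlation_matrix(
    layers: dict[str, pd.DataFrame], support: str = "union_nonzero"
) -> CorrelationMatrix:
    """Pairwise Pearson r (with two-sided p) among the 9 layer-metric vectors.

    ``support="union_nonzero"`` restricts each pair to cells where at least
    one of the two layers has records, so the vast empty ocean does not
    inflate the correlations; ``"all_cells"`` uses every cell. A
    zero-variance vector makes r undefined for its pairs (reported as NaN).
    """
    if support not in ("union_nonzero", "all_cells"):
        raise ValueError(f"unknown support rule {support!r}")
    cols: dict[str, pd.Series] = {}
    nonzero: dict[str, pd.Series] = {}
    for layer in LAYERS:
        if layer not in layers:
            raise ValueError(f"missing layer {layer!r}")
        for metric in METRICS:
            name = f"{layer}_{metric}"
            cols[name] = layers[layer][metric].astype(float)
            nonzero[name] = layers[layer]["SE"] > 0
    names = list(cols)
    r = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names)
    for a in names:
        for b in names:
            if support == "union_nonzero":
                mask = (nonzero[a] | nonzero[b]).to_numpy()
            else:
                mask = np.ones(len(cols[a]), dtype=bool)
            x, y = cols[a].to_numpy()[mask], cols[b].to_numpy()[mask]
            n.loc[a, b] = int(mask.sum())
            if mask.sum() < 3 or np.std(x) == 0 or np.std(y) == 0:
                continue
            if a == b:
                r.loc[a, b], p.loc[a, b] = 1.0, 0.0
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b], p.loc[a, b] = float(res.statistic), float(res.pvalue)
    return CorrelationMatrix(r=r, p=p, n=n, support=support)
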