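"""coeff*stddev contour maps: where the model says bulk/charge/etc. helps.

For every kept grid column j of a field, the map value is b_j · sd_j — the
PLS regression coefficient times the column standard deviation — so the map
highlights lattice regions whose field variation drives predicted activity.
Favored/disfavored regions are the points above the 80% and below the 20%
levels of the kept-value distribution (value quantiles by default; a
cumulative-contribution mode is available).  Maps export to OpenDX scalar
grids with a JSON sidecar carrying thresholds and masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .field_engine import Lattice
from .qsar_stats import DescriptorMatrix, PLSModel


@dataclass
class ContourMap:
    """Per-grid-point b·sd values with favored/disfavored masks.

    ``values`` covers the full lattice (dropped columns are zero and are
    excluded from thresholding via ``kept_mask``).
    """

    field_kind: str
    lattice: Lattice
    values: np.ndarray          # (n_points,)
    kept_mask: np.ndarray       # (n_points,) bool
    favored_threshold: float | None = None
    disfavored_threshold: float | None = None
    favored_mask: np.ndarray | None = None
    disfavored_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def stdev_coeff_map(
    model: PLSModel, M: DescriptorMatrix, field_kind: str
) -> ContourMap:
    """Map value_j = coefficient_j × column standard deviation (training rows)."""
    if field_kind not in model.field_kinds:
        raise ValueError(f"field {field_kind!r} not present in the model")
    cols = M.columns_of_kind(field_kind)
    sd = M.X_raw[np.ix_(model.train_rows, cols)].std(axis=0, ddof=1)
    vals = model.coef[cols] * sd
    full = np.zeros(M.lattice.n_points)
    kept = np.zeros(M.lattice.n_points, dtype=bool)
    grid_idx = np.array([M.column_labels[c][1] for c in cols], dtype=int)
    full[grid_idx] = vals
    kept[grid_idx] = True
    return ContourMap(field_kind=field_kind, lattice=M.lattice, values=full, kept_mask=kept)


def contour_levels(
    cmap: ContourMap,
    favored_fraction: float = 0.80,
    disfavored_fraction: float = 0.20,
    mode: str = "quantile",
) -> ContourMap:
    """Threshold a map into favored and disfavored point masks.

    ``quantile`` (default): favored points have values at or above the
    favored_fraction quantile of the kept values (linear interpolation);
    disfavored at or below the disfavored_fraction quantile.  ``cumulative``
    instead takes the smallest sets of extreme points accounting for the top
    (1−favored_fraction) and bottom disfavored_fraction shares of Σ|value|.
    """
    kept_vals = cmap.values[cmap.kept_mask]
    if kept_vals.size == 0:
        raise ValueError("contour map has no kept values")
    favored = np.zeros_like(cmap.kept_mask)
    disfavored = np.zeros_like(cmap.kept_mask)
    if np.allclose(kept_vals, kept_vals[0]):
        warnings.warn(f"{cmap.field_kind}: all map values equal; empty contour masks")
        hi = lo = None
    elif mode == "quantile":
        hi = float(np.quantile(kept_vals, favored_fraction, method="linear"))
        lo = float(np.quantile(kept_vals, disfavored_fraction, method="linear"))
        favored = cmap.kept_mask & (cmap.values >= hi)
        disfavored = cmap.kept_mask & (cmap.values <= lo)
    elif mode == "cumulative":
        idx = np.flatnonzero(cmap.kept_mask)
        order = idx[np.argsort(cmap.values[idx])]
        absv = np.abs(cmap.values[order])
        total = absv.sum()
        tol = 1e-9 * total
        top_share = (1.0 - favored_fraction) * total + tol
        bot_share = disfavored_fraction * total + tol
        cum_from_top = np.cumsum(absv[::-1])[::-1]
        cum_from_bot = np.cumsum(absv)
        favored[order[cum_from_top <= top_share]] = True
        disfavored[order[cum_from_bot <= bot_share]] = True
        hi = float(cmap.values[favored].min()) if favored.any() else None
        lo = float(cmap.values[disfavored].max()) if disfavored.any() else None
    else:
        raise ValueError(f"unknown contour mode {mode!r}")
    overlap = favored & disfavored
    if overlap.any():
        favored &= ~overlap
        disfavored &= ~overlap
    return ContourMap(
        field_kind=cmap.field_kind,
        lattice=cmap.lattice,
        values=cmap.values,
        kept_mask=cmap.kept_mask,
        favored_threshold=hi,
        disfavored_threshold=lo,
        favored_mask=favored,
        disfavored_mask=disfavored,
        meta={**cmap.meta, "mode": mode,
              "favored_fraction": favored_fraction,
              "disfavored_fraction": disfavored_fraction},
    )


def export_grid(cmap: ContourMap, path: str, format: str = "dx") -> None:
    """Write the map as an OpenDX regular scalar grid plus a JSON sidecar.

    The sidecar (<path>.json) records thresholds, masks (point indices) and
    the lattice header; re-import reproduces values to 1e−6.
    """
    if format.lower() != "dx":
        raise ValueError(f"unsupported export format {format!r}")
    from gridData import Grid

    shaped = cmap.values.reshape(cmap.lattice.dims)
    g = Grid(shaped, origin=np.asarray(cmap.lattice.origin),
             delta=cmap.lattice.spacing)
    g.export(str(path), file_format="DX")
    sidecar = {
        "field_kind": cmap.field_kind,
        "lattice": cmap.lattice.header(),
        "favored_threshold": cmap.favored_threshold,
        "disfavored_threshold": cmap.disfavored_threshold,
        "favored_points": (
            np.flatnonzero(cmap.favored_mask).tolist()
            if cmap.favored_mask is not None else None
        ),
        "disfavored_points": (
            np.flatnonzero(cmap.disfavored_mask).tolist()
            if cmap.disfavored_mask is not None else None
        ),
        "kept_points": np.flatnonzero(cmap.kept_mask).tolist(),
        "meta": cmap.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def import_grid(path: str) -> ContourMap:
    """Reload an exported map (values, lattice, thresholds, masks)."""
    from gridData import Grid

    g = Grid(str(path))
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    lattice = Lattice.from_header(sidecar["lattice"])
    values = np.asarray(g.grid).reshape(-1)
    n = lattice.n_points
    kept = np.zeros(n, dtype=bool)
    kept[sidecar["kept_points"]] = True
    fav = dis = None
    if sidecar["favored_points"] is not None:
        fav = np.zeros(n, dtype=bool)
        fav[sidecar["favored_points"]] = True
    if sidecar["disfavored_points"] is not None:
        dis = np.zeros(n, dtype=bool)
        dis[sidecar["disfavored_points"]] = True
    return ContourMap(
        field_kind=sidecar["field_kind"],
        lattice=lattice,
        values=values,
        kept_mask=kept,
        favored_threshold=sidecar["favored_threshold"],
        disfavored_threshold=sidecar["disfavored_threshold"],
        favored_mask=fav,
        disfavored_mask=dis,
        meta=sidecar.get("meta", {}),
    )


def export_csv(cmap: ContourMap, path: str) -> None:
    """Dump (x, y, z, value, mask) rows for external plotting."""
    pts = cmap.lattice.points()
    mask = np.full(cmap.values.shape, "", dtype=object)
    if cmap.favored_mask is not None:
        mask[cmap.favored_mask] = "favored"
    if cmap.disfavored_mask is not None:
        mask[cmap.disfavored_mask] = "disfavored"
    import pandas as pd

    pd.DataFrame(
        {
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "value": cmap.values, "mask": mask,
        }
    ).to_csv(path, index=False)
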