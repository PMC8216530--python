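"""Environmental predictor engineering.

Regridding to the 0.08 degree analysis grid, moving-window
proportional-change gradients (front/slope proxies), nearest-cell
extraction at GPS fixes, and iterative variance-inflation-factor screening
of the covariate table.  Rasters travel as xarray DataArrays (dims lat,
lon, NaN = missing) and persist as plain-text ESRI ASCII grids.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import maximum_filter, minimum_filter

from .config import GRID_RES_DEG

DYNAMIC_VARS = ("SST", "CHLA", "SSH", "OMLT")
ALL_VARS = ("DEP",) + DYNAMIC_VARS
GRADIENT_NAMES = {v: f"G{v}" for v in ALL_VARS}


# ---------------------------------------------------------------- raster I/O

def write_ascii_grid(da: xr.DataArray, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a (lat, lon) DataArray as an ESRI ASCII grid (cell-center registered)."""
    da = da.sortby("lat")
    res = float(da.lon[1] - da.lon[0]) if da.lon.size > 1 else GRID_RES_DEG
    vals = np.where(np.isfinite(da.values), da.values, nodata)
    header = (
        f"ncols {da.lon.size}\n"
        f"nrows {da.lat.size}\n"
        f"xllcenter {float(da.lon[0]):.10f}\n"
        f"yllcenter {float(da.lat[0]):.10f}\n"
        f"cellsize {res:.10f}\n"
        f"nodata_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6g")  # north-up row order


def read_ascii_grid(path: str | Path) -> xr.DataArray:
    """Read an ESRI ASCII grid into a (lat, lon) DataArray with NaN missing."""
    head: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    ncols, nrows = int(head["ncols"]), int(head["nrows"])
    res = head["cellsize"]
    x0 = head.get("xllcenter", head.get("xllcorner", 0.0) + res / 2)
    y0 = head.get("yllcenter", head.get("yllcorner", 0.0) + res / 2)
    vals = np.where(vals == head.get("nodata_value", -9999.0), np.nan, vals)
    return xr.DataArray(
        vals,
        dims=("lat", "lon"),
        coords={
            "lat": y0 + res * np.arange(nrows),
            "lon": x0 + res * np.arange(ncols),
        },
    )


# ---------------------------------------------------------------- gradients

def gradient_pc(raster: xr.DataArray) -> xr.DataArray:
    """Proportional change over a 3x3 moving window, per cell, in percent.

    PC = (window max - window min) * 100 / window max.  Windows are
    truncated at the raster edge.  Cells whose window maximum is <= 0, or
    whose window holds only missing values, are set missing — the formula
    is not meaningful for non-positive maxima (e.g. negative sea-surface
    heights); an ``offset_to_positive`` shift can be applied upstream.
    """
    v = raster.values.astype(float)
    finite = np.isfinite(v)
    vmax = maximum_filter(np.where(finite, v, -np.inf), size=3, mode="constant", cval=-np.inf)
    vmin = minimum_filter(np.where(finite, v, np.inf), size=3, mode="constant", cval=np.inf)
    valid = np.isfinite(vmax) & np.isfinite(vmin) & (vmax > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = np.where(valid, (vmax - vmin) * 100.0 / vmax, np.nan)
    return xr.DataArray(pc, dims=raster.dims, coords=raster.coords, name=f"G{raster.name or ''}")


def gradient_stack(env: xr.Dataset) -> xr.Dataset:
    """PC gradients of every layer in an environment Dataset (G-prefixed)."""
    out = {}
    for name, da in env.data_vars.items():
        if "month" in da.dims:
            out[f"G{name}"] = da.groupby("month").map(gradient_pc)
        else:
            out[f"G{name}"] = gradient_pc(da)
    return xr.Dataset(out, coords=env.coords)


# ---------------------------------------------------------------- regridding

def regrid(raster: xr.DataArray, target_res: float = GRID_RES_DEG) -> xr.DataArray:
    """Resample a regular (lat, lon) raster to ``target_res``.

    Coarsening aggregates by block means over nearest target cells
    (missing cells excluded); refining interpolates bilinearly.  A source
    already at the target resolution passes through unchanged.
    """
    res = float(raster.lon[1] - raster.lon[0])
    if np.isclose(res, target_res, rtol=1e-6):
        return raster
    lon0, lon1 = float(raster.lon.min()), float(raster.lon.max())
    lat0, lat1 = float(raster.lat.min()), float(raster.lat.max())
    new_lon = np.arange(lon0 - res / 2 + target_res / 2, lon1 + res / 2, target_res)
    new_lat = np.arange(lat0 - res / 2 + target_res / 2, lat1 + res / 2, target_res)
    if len(new_lon) == 0 or len(new_lat) == 0:
        raise ValueError("empty overlap with target grid")
    if target_res > res:  # coarsen: mean of source cells nearest each target cell
        ilon = np.clip(np.round((raster.lon.values - new_lon[0]) / target_res), 0, len(new_lon) - 1).astype(int)
        ilat = np.clip(np.round((raster.lat.values - new_lat[0]) / target_res), 0, len(new_lat) - 1).astype(int)
        vals = raster.values
        acc = np.zeros((len(new_lat), len(new_lon)))
        cnt = np.zeros_like(acc)
        finite = np.isfinite(vals)
        np.add.at(acc, (ilat[:, None].repeat(len(ilon), 1), ilon[None, :].repeat(len(ilat), 0)), np.where(finite, vals, 0.0))
        np.add.at(cnt, (ilat[:, None].repeat(len(ilon), 1), ilon[None, :].repeat(len(ilat), 0)), finite.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cnt > 0, acc / cnt, np.nan)
        return xr.DataArray(out, dims=("lat", "lon"), coords={"lat": new_lat, "lon": new_lon}, name=raster.name)
    return raster.interp(lon=new_lon, lat=new_lat, method="linear").rename(raster.name)


# ---------------------------------------------------------------- extraction

def extract_at(fixes: pd.DataFrame, env: xr.Dataset, gradients: xr.Dataset | None = None) -> pd.DataFrame:
    """Nearest-cell covariates for each fix, month-matched for dynamic layers.

    Returns ``fixes`` with one column per static, dynamic and gradient
    layer; fixes outside the raster extent get missing values (with a
    warning).  Extraction is nearest-cell, matching raster-resolution
    habitat analysis.
    """
    if gradients is None:
        gradients = gradient_stack(env)
    stack = xr.merge([env, gradients])
    out = fixes.copy()
    months = pd.to_datetime(out["timestamp"]).dt.month.to_numpy()
    lon = xr.DataArray(out["lon"].to_numpy(float), dims="fix")
    lat = xr.DataArray(out["lat"].to_numpy(float), dims="fix")
    res = float(stack.lon[1] - stack.lon[0]) if stack.lon.size > 1 else GRID_RES_DEG
    outside = (
        (out["lon"] < float(stack.lon.min()) - res / 2)
        | (out["lon"] > float(stack.lon.max()) + res / 2)
        | (out["lat"] < float(stack.lat.min()) - res / 2)
        | (out["lat"] > float(stack.lat.max()) + res / 2)
    ).to_numpy()
    if outside.any():
        import warnings

        warnings.warn(f"{int(outside.sum())} fixes outside raster extent; values set missing")
    for name, da in stack.data_vars.items():
        if "month" in da.dims:
            avail = set(int(m) for m in da.month.values)
            missing_months = set(months) - avail
            if missing_months:
                raise ValueError(f"no {name} layers for months {sorted(missing_months)}")
            sel = da.sel(month=xr.DataArray(months, dims="fix")).sel(
                lon=lon, lat=lat, method="nearest"
            )
        else:
            sel = da.sel(lon=lon, lat=lat, method="nearest")
        vals = sel.values.astype(float)
        vals[outside] = np.nan
        out[name] = vals
    return out


# ---------------------------------------------------------------- VIF screen

def vif_screen(
    covariates: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF covariate while any VIF > threshold.

    VIF_j = 1/(1 - R2_j) from regressing covariate j on the others (with
    intercept); perfect collinearity maps to infinite VIF and is dropped
    first.  Ties break alphabetically so results are column-order
    independent.  Returns the retained names and a per-round VIF report.
    """
    cols = sorted(covariates.columns)
    x = covariates[cols].dropna()
    if len(x) < len(cols) + 2:
        raise ValueError("need at least 2 more complete rows than variables")
    active = list(cols)
    report_rows = []
    rnd = 0
    while True:
        vifs = {}
        for c in active:
            others = [o for o in active if o != c]
            if not others:
                vifs[c] = 1.0
                continue
            a = np.column_stack([np.ones(len(x))] + [x[o].to_numpy(float) for o in others])
            y = x[c].to_numpy(float)
            coef, *_ = np.linalg.lstsq(a, y, rcond=None)
            resid = y - a @ coef
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
            vifs[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        for c in active:
            report_rows.append({"round": rnd, "variable": c, "vif": vifs[c]})
        worst = max(active, key=lambda c: (vifs[c], c))
        if vifs[worst] > threshold:
            active.remove(worst)
            rnd += 1
            if len(active) == 1:
                report_rows.append({"round": rnd, "variable": active[0], "vif": 1.0})
                break
        else:
            break
    return active, pd.DataFrame(report_rows)
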