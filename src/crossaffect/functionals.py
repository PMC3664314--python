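"""Suprasegmental functionals: contour -> fixed-length feature vector.

Each of the 64 LLD contours (and its delta-regression contour) is summarized
by a bank of statistical functionals drawn from six families — percentiles,
moments, temporal, modulation (linear prediction), peaks and regression.
The composed feature space has exactly 6373 dimensions; the bookkeeping is
pinned by :func:`build_feature_index` and shipped as a manifest:

* every LLD: 35 functionals (percentiles, moments, temporal, modulation) on
  the contour and on its delta, plus 19 LLD-only functionals (peaks,
  regression, fraction of non-zero frames);
* the delta contours of the 59 energy+spectral LLDs additionally receive the
  peaks block (peak structure of descriptor *change*, e.g. delta-loudness
  peak distances);
* the delta contours of the 4 energy LLDs additionally receive the
  regression block.

64*89 + 59*11 + 4*7 = 6373.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz

from .lld import LLD_CATEGORY, LLD_GROUPS, LLD_NAMES, LLDMatrix

EPS = 1e-12

PERCENTILE_FUNCS = ["quartile_1", "quartile_2", "quartile_3",
                    "iqr_1_2", "iqr_2_3", "iqr_1_3",
                    "percentile_1", "percentile_99", "range_1_99"]
MOMENT_FUNCS = ["mean_arith", "mean_rq", "stddev", "skewness", "kurtosis"]
TEMPORAL_FUNCS = ["pos_min", "pos_max", "range", "contour_centroid",
                  "flatness", "updur_25", "updur_50", "updur_75", "updur_90",
                  "rise_dur", "curve_up_dur",
                  "seg_len_mean", "seg_len_max", "seg_len_min", "seg_len_std"]
MODULATION_FUNCS = ["lp_gain", "lp_c1", "lp_c2", "lp_c3", "lp_c4", "lp_c5"]
PEAK_FUNCS = ["peak_val_mean", "peak_val_minus_mean",
              "peak_dist_mean", "peak_dist_std",
              "peak_amp_mean", "min_amp_mean", "peak_amp_range",
              "rslope_mean", "rslope_std", "fslope_mean", "fslope_std"]
REGRESSION_FUNCS = ["lin_slope", "lin_offset", "lin_err",
                    "quad_a", "quad_b", "quad_offset", "quad_err"]

BLOCK_A = PERCENTILE_FUNCS + MOMENT_FUNCS + TEMPORAL_FUNCS + MODULATION_FUNCS
BLOCK_B = PEAK_FUNCS + REGRESSION_FUNCS + ["nonzero_frac"]

FUNCTIONAL_FAMILY: dict[str, str] = {}
for _f in PERCENTILE_FUNCS:
    FUNCTIONAL_FAMILY[_f] = "percentiles"
for _f in MOMENT_FUNCS:
    FUNCTIONAL_FAMILY[_f] = "moments"
for _f in TEMPORAL_FUNCS + ["nonzero_frac"]:
    FUNCTIONAL_FAMILY[_f] = "temporal"
for _f in MODULATION_FUNCS:
    FUNCTIONAL_FAMILY[_f] = "modulation"
for _f in PEAK_FUNCS:
    FUNCTIONAL_FAMILY[_f] = "peaks"
for _f in REGRESSION_FUNCS:
    FUNCTIONAL_FAMILY[_f] = "regression"

FUNCTIONAL_FAMILIES = ("percentiles", "temporal", "moments", "modulation",
                       "peaks", "regression")


# ---------------------------------------------------------------------------
# contour-level operations (all accept 1-D contours; *_mat variants operate
# column-wise on 2-D arrays and are what the extractor uses)

def delta_contour(x: np.ndarray) -> np.ndarray:
    """First-order regression delta with a 2-frame symmetric context.

    Edges are replicated so the delta has the length of the input; a
    length-1 contour has an all-zero delta.  A linear ramp of slope m per
    frame yields a constant interior delta of m.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    if x.shape[0] < 2:
        d = np.zeros_like(x)
        return d[:, 0] if squeeze else d
    pad = np.pad(x, ((2, 2), (0, 0)), mode="edge")
    d = (1.0 * (pad[3:-1] - pad[1:-3]) + 2.0 * (pad[4:] - pad[:-4])) / 10.0
    return d[:, 0] if squeeze else d


def _as2d(x):
    x = np.asarray(x, dtype=float)
    return (x[:, None], True) if x.ndim == 1 else (x, False)


def percentiles_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    q = np.percentile(X, [25, 50, 75, 1, 99], axis=0, method="linear")
    return {
        "quartile_1": q[0], "quartile_2": q[1], "quartile_3": q[2],
        "iqr_1_2": q[1] - q[0], "iqr_2_3": q[2] - q[1], "iqr_1_3": q[2] - q[0],
        "percentile_1": q[3], "percentile_99": q[4], "range_1_99": q[4] - q[3],
    }


def moments_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    mean = X.mean(axis=0)
    rq = np.sqrt((X ** 2).mean(axis=0))
    c = X - mean
    var = (c ** 2).mean(axis=0)
    sd = np.sqrt(var)
    # snap float-noise deviations of a constant contour to exactly 0
    sd = np.where(sd > 1e-12 * (1.0 + np.abs(mean)), sd, 0.0)
    ok = sd > EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, (c ** 3).mean(axis=0) / np.maximum(sd, EPS) ** 3, 0.0)
        kurt = np.where(ok, (c ** 4).mean(axis=0) / np.maximum(var, EPS) ** 2, 0.0)
    return {"mean_arith": mean, "mean_rq": rq, "stddev": sd,
            "skewness": skew, "kurtosis": kurt}


def _segment_lengths(above: np.ndarray) -> list[np.ndarray]:
    """Run lengths of True values, per column."""
    n, m = above.shape
    out = []
    for j in range(m):
        a = above[:, j]
        if not a.any():
            out.append(np.empty(0))
            continue
        edges = np.diff(np.concatenate(([0], a.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        out.append((ends - starts).astype(float))
    return out


def temporal_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    n, m = X.shape
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    rng = hi - lo
    denom = max(n - 1, 1)
    out = {
        "pos_min": X.argmin(axis=0) / denom,
        "pos_max": X.argmax(axis=0) / denom,
        "range": rng,
    }
    # contour centroid on normalized time after a non-negative shift
    t = np.arange(n) / denom if n > 1 else np.zeros(1)
    shifted = X - lo
    mass = shifted.sum(axis=0)
    out["contour_centroid"] = np.where(
        mass > EPS, (t[:, None] * shifted).sum(axis=0) / np.maximum(mass, EPS),
        0.5)
    absx = np.abs(X) + EPS
    out["flatness"] = np.exp(np.log(absx).mean(axis=0)) / absx.mean(axis=0)
    for q in (0.25, 0.50, 0.75, 0.90):
        out[f"updur_{int(q * 100)}"] = (X > lo + q * rng).mean(axis=0)
    if n > 1:
        d = np.diff(X, axis=0)
        out["rise_dur"] = (d > 0).mean(axis=0)
    else:
        out["rise_dur"] = np.zeros(m)
    if n > 2:
        d2 = np.diff(X, n=2, axis=0)
        out["curve_up_dur"] = (d2 > 0).mean(axis=0)
    else:
        out["curve_up_dur"] = np.zeros(m)
    segs = _segment_lengths(X > lo + 0.25 * rng)
    for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min),
                     ("std", np.std)):
        out[f"seg_len_{stat}"] = np.array(
            [fn(s) if s.size else 0.0 for s in segs])
    out["nonzero_frac"] = (X != 0).mean(axis=0)
    return out


def modulation_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    """Order-5 linear prediction (autocorrelation method) on the
    mean-removed contour; gain is the residual (prediction error) energy."""
    n, m = X.shape
    order = 5
    out = {k: np.zeros(m) for k in MODULATION_FUNCS}
    if n <= order:
        return out
    C = X - X.mean(axis=0)
    for j in range(m):
        x = C[:, j]
        r = np.array([x[:n - k] @ x[k:] for k in range(order + 1)]) / n
        if not np.all(np.isfinite(r)) or r[0] <= EPS:
            continue
        try:
            a = solve_toeplitz((r[:order], r[:order]), r[1:order + 1])
        except (np.linalg.LinAlgError, ValueError):
            continue
        out["lp_gain"][j] = max(r[0] - a @ r[1:order + 1], 0.0)
        for k in range(order):
            out[f"lp_c{k + 1}"][j] = a[k]
    return out


def _extrema_masks(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean frame-by-contour masks of local maxima/minima; on plateaus
    the earliest frame wins (sign of the next non-zero difference)."""
    n, m = X.shape
    peaks = np.zeros((n, m), dtype=bool)
    mins = np.zeros((n, m), dtype=bool)
    if n < 3:
        return peaks, mins
    d = np.diff(X, axis=0)
    s = np.sign(d)
    # backward-fill zeros of s along time: index of next nonzero diff
    row = np.arange(d.shape[0])[:, None]
    idx = np.where(s != 0, row, d.shape[0])
    nxt_idx = np.minimum.accumulate(idx[::-1], axis=0)[::-1]
    valid = nxt_idx < d.shape[0]
    nxt = np.zeros_like(s)
    cols = np.broadcast_to(np.arange(m), nxt_idx.shape)
    nxt[valid] = s[nxt_idx[valid], cols[valid]]
    interior = slice(1, n - 1)
    peaks[interior] = (d[:-1] > 0) & (nxt[1:] < 0)
    mins[interior] = (d[:-1] < 0) & (nxt[1:] > 0)
    return peaks, mins


def _masked_col_stats(vals: np.ndarray, mask: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise count, mean and SD of ``vals`` where ``mask``; 0 when
    the mask selects nothing."""
    cnt = mask.sum(axis=0)
    safe = np.maximum(cnt, 1)
    mean = np.where(mask, vals, 0.0).sum(axis=0) / safe
    msq = np.where(mask, vals ** 2, 0.0).sum(axis=0) / safe
    sd = np.sqrt(np.maximum(msq - mean ** 2, 0.0))
    zero = cnt == 0
    mean[zero] = 0.0
    sd[zero] = 0.0
    return cnt, mean, sd


def peaks_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    """Peak functionals.  A peak is a local maximum exceeding the contour
    mean; a contour with no such peak yields zeros for the whole block.
    Distances are in frames, slopes in units/frame (slopes are the positive
    and negative consecutive-frame differences)."""
    n, m = X.shape
    out = {k: np.zeros(m) for k in PEAK_FUNCS}
    means = X.mean(axis=0)
    lows = X.min(axis=0)
    pk_mask, mn_mask = _extrema_masks(X)
    pk_mask &= X > means
    mn_mask &= X < means

    pcnt, pmean, _ = _masked_col_stats(X, pk_mask)
    has_pk = pcnt > 0
    out["peak_val_mean"] = np.where(has_pk, pmean, 0.0)
    out["peak_val_minus_mean"] = np.where(has_pk, pmean - means, 0.0)
    out["peak_amp_mean"] = np.where(has_pk, pmean - lows, 0.0)
    pmax = np.where(pk_mask, X, -np.inf).max(axis=0)
    pmin = np.where(pk_mask, X, np.inf).min(axis=0)
    out["peak_amp_range"] = np.where(has_pk, pmax - pmin, 0.0)
    mcnt, mmean, _ = _masked_col_stats(X, mn_mask)
    out["min_amp_mean"] = np.where(mcnt > 0, mmean - lows, 0.0)

    # inter-peak distances need the ragged per-column peak index lists
    cols, rows = np.nonzero(pk_mask.T)
    bounds = np.searchsorted(cols, np.arange(m + 1))
    for j in range(m):
        a, b = bounds[j], bounds[j + 1]
        if b - a > 1:
            dist = np.diff(rows[a:b]).astype(float)
            out["peak_dist_mean"][j] = dist.mean()
            out["peak_dist_std"][j] = dist.std()

    if n > 1:
        d = np.diff(X, axis=0)
        _, rmean, rsd = _masked_col_stats(d, d > 0)
        _, fmean, fsd = _masked_col_stats(d, d < 0)
        out["rslope_mean"], out["rslope_std"] = rmean, rsd
        out["fslope_mean"], out["fslope_std"] = fmean, fsd
    return out


def regression_block_mat(X: np.ndarray) -> dict[str, np.ndarray]:
    """Least-squares line/parabola fits over normalized time t in [0, 1];
    offsets are the fitted values at t=0, errors the mean squared residual."""
    n, m = X.shape
    out = {k: np.zeros(m) for k in REGRESSION_FUNCS}
    if n == 1:
        out["lin_offset"] = X[0].copy()
        out["quad_offset"] = X[0].copy()
        return out
    t = np.linspace(0.0, 1.0, n)
    lin = np.polyfit(t, X, 1)
    out["lin_slope"], out["lin_offset"] = lin[0], lin[1]
    fit = np.outer(t, lin[0]) + lin[1]
    out["lin_err"] = ((X - fit) ** 2).mean(axis=0)
    if n >= 3:
        quad = np.polyfit(t, X, 2)
        out["quad_a"], out["quad_b"], out["quad_offset"] = quad
        fit2 = np.outer(t ** 2, quad[0]) + np.outer(t, quad[1]) + quad[2]
        out["quad_err"] = ((X - fit2) ** 2).mean(axis=0)
    return out


def _scalar_wrap(fn, contour):
    X, _ = _as2d(np.asarray(contour, dtype=float))
    return {k: float(v[0]) for k, v in fn(X).items()}


def percentiles_block(contour):
    return _scalar_wrap(percentiles_block_mat, contour)


def moments_block(contour):
    return _scalar_wrap(moments_block_mat, contour)


def temporal_block(contour):
    return _scalar_wrap(temporal_block_mat, contour)


def modulation_block(contour):
    return _scalar_wrap(modulation_block_mat, contour)


def peaks_block(contour):
    return _scalar_wrap(peaks_block_mat, contour)


def regression_block(contour):
    return _scalar_wrap(regression_block_mat, contour)


# ---------------------------------------------------------------------------
# feature index (the versioned manifest) and vector assembly

@dataclass
class FeatureIndex:
    """Per-dimension metadata for the composed feature space."""

    table: pd.DataFrame   # columns: name, lld, lld_group, lld_category,
                          # functional, family, is_delta

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)

    def subset(self, mask_or_names) -> pd.DataFrame:
        if isinstance(mask_or_names, (list, np.ndarray, pd.Index)) and \
                len(mask_or_names) and isinstance(mask_or_names[0], str):
            return self.table[self.table["name"].isin(mask_or_names)]
        return self.table[mask_or_names]


def build_feature_index() -> FeatureIndex:
    rows = []

    def add(lld, func, is_delta):
        prefix = f"{lld}.delta" if is_delta else lld
        rows.append({
            "name": f"{prefix}.{func}",
            "lld": lld,
            "lld_group": LLD_GROUPS[lld],
            "lld_category": LLD_CATEGORY[lld],
            "functional": func,
            "family": FUNCTIONAL_FAMILY[func],
            "is_delta": is_delta,
        })

    for lld in LLD_NAMES:
        cat = LLD_CATEGORY[lld]
        for func in BLOCK_A:
            add(lld, func, False)
        for func in BLOCK_A:
            add(lld, func, True)
        for func in BLOCK_B:
            add(lld, func, False)
        if cat in ("energy", "spectral"):
            for func in PEAK_FUNCS:
                add(lld, func, True)
        if cat == "energy":
            for func in REGRESSION_FUNCS:
                add(lld, func, True)
    table = pd.DataFrame(rows)
    if table["name"].duplicated().any():
        raise RuntimeError("duplicate feature names in manifest")
    return FeatureIndex(table)


FEATURE_DIM = 6373


@dataclass
class FeatureVector:
    values: np.ndarray
    clip_id: str = ""


_ALL_BLOCKS = (percentiles_block_mat, moments_block_mat, temporal_block_mat,
               modulation_block_mat, peaks_block_mat, regression_block_mat)


def extract_features(lld: LLDMatrix, index: FeatureIndex | None = None
                     ) -> FeatureVector:
    """Apply the functional bank to every LLD contour and its delta."""
    if index is None:
        index = build_feature_index()
    V = lld.values
    D = delta_contour(V)
    # functional name -> 64-vector, separately for contour and delta
    table: dict[tuple[str, bool], np.ndarray] = {}
    for mat, is_delta in ((V, False), (D, True)):
        for block in _ALL_BLOCKS:
            for fname, vals in block(mat).items():
                table[(fname, is_delta)] = vals

    key_list = sorted(table)
    plan = getattr(index, "_gather_plan", None)
    if plan is None or plan[0] != lld.names or plan[1] != key_list:
        col_of = {name: i for i, name in enumerate(lld.names)}
        key_of = {k: i for i, k in enumerate(key_list)}
        tab = index.table
        lld_idx = tab["lld"].map(col_of).to_numpy()
        key_idx = np.array([key_of[k] for k in
                            zip(tab["functional"], tab["is_delta"])])
        plan = (list(lld.names), key_list, key_idx, lld_idx)
        index._gather_plan = plan
    _, _, key_idx, lld_idx = plan
    B = np.stack([table[k] for k in key_list])
    out = B[key_idx, lld_idx]
    bad = ~np.isfinite(out)
    if bad.any():
        name = index.table["name"].iloc[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-finite feature value in dimension {name!r}")
    return FeatureVector(out, clip_id=lld.clip_id)


def features_to_frame(vectors: list[FeatureVector],
                      index: FeatureIndex) -> pd.DataFrame:
    df = pd.DataFrame([v.values for v in vectors], columns=index.names)
    df.insert(0, "clip_id", [v.clip_id for v in vectors])
    return df
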