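"""Correlation-based screening of spectral features against LAI.

Every candidate feature — a (differentiation order, band) cell of a
derivative stack or a (scale, band) cell of a wavelet scalogram — is
Pearson-correlated with the per-plot LAI.  Significance is assessed with
the exact two-tailed t-test, t = rho * sqrt((n-2)/(1-rho^2)) on n-2
degrees of freedom; the analysis counts bands passing the 0.01 level per
order/scale and selects the top-k features by |rho| (default k = 10).

Feature labels follow the field convention: differential spectra are
"J<order>R<band>" (e.g. J1.1R708 = order-1.1 derivative at 708 nm) and
wavelet energy coefficients "C<scale>R<band>" (e.g. C7R725 = scale label 7
at 725 nm).  No multiple-testing correction is applied; with ~1001 bands
per order the 1% level admits ~10 false positives per row on pure noise —
a statistical caveat inherited from the screening design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cwt import WaveletScalogram
from .fracdiff import DerivativeStack


def pearson_with_pvalues(X: np.ndarray, y: np.ndarray):
    """Column-wise Pearson rho of X (n_samples, n_features) against y,
    with exact two-tailed p-values.  Zero-variance columns are masked
    (returned invalid), not reported as rho = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 samples for screening")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    valid = (sx > 0) & (sy > 0)
    rho = np.full(X.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho[valid] = (Xc[:, valid] * yc[:, None]).sum(axis=0) / (sx[valid] * sy)
    rho = np.clip(rho, -1.0, 1.0)
    p = np.full(X.shape[1], np.nan)
    r = rho[valid]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p[valid] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return rho, p, valid


@dataclass
class CorrelationMap:
    """Per (order-or-scale, band) Pearson rho and p-value against LAI."""

    kind: str  # 'fracdiff' | 'wavelet'
    row_labels: np.ndarray  # orders (float) or scale labels (int)
    wavelengths: np.ndarray
    rho: np.ndarray  # (n_rows, n_bands)
    p: np.ndarray
    valid: np.ndarray
    n_samples: int


def correlate_with_lai(
    source: DerivativeStack | WaveletScalogram,
    lai: np.ndarray,
    sample_idx: np.ndarray | None = None,
) -> CorrelationMap:
    """Correlate every valid cell of a stack/scalogram with LAI.

    ``sample_idx`` restricts the correlation to a subset of samples (the
    modeling partition, when screening feeds feature selection); ``lai``
    must then be the matching subset of LAI values.
    """
    if isinstance(source, DerivativeStack):
        kind, rows, data, upstream = "fracdiff", source.orders, source.data, source.valid
    elif isinstance(source, WaveletScalogram):
        kind, rows, data, upstream = (
            "wavelet", source.scale_labels, source.coefficients, source.valid,
        )
    else:
        raise TypeError("source must be a DerivativeStack or WaveletScalogram")
    lai = np.asarray(lai, dtype=float)
    if sample_idx is not None:
        data = data[:, np.asarray(sample_idx), :]
    n_rows, n_samples, n_bands = data.shape
    if lai.size != n_samples:
        raise ValueError("lai length must match the (sub)sample count")
    rho = np.full((n_rows, n_bands), np.nan)
    p = np.full((n_rows, n_bands), np.nan)
    valid = np.zeros((n_rows, n_bands), dtype=bool)
    for i in range(n_rows):
        r_i, p_i, v_i = pearson_with_pvalues(data[i], lai)
        v_i &= upstream[i]
        rho[i, v_i] = r_i[v_i]
        p[i, v_i] = p_i[v_i]
        valid[i] = v_i
    return CorrelationMap(kind, np.asarray(rows), source.wavelengths, rho, p, valid, n_samples)


def significance_mask(cmap: CorrelationMap, level: float = 0.01):
    """Boolean mask of cells passing p < level, plus per-row counts."""
    mask = np.zeros_like(cmap.valid)
    mask[cmap.valid] = cmap.p[cmap.valid] < level
    return mask, mask.sum(axis=1)


def feature_label(kind: str, order_or_scale, wavelength) -> str:
    wl = int(round(float(wavelength)))
    if kind == "fracdiff":
        return f"J{float(order_or_scale):.1f}R{wl}"
    if kind == "wavelet":
        return f"C{int(order_or_scale)}R{wl}"
    raise ValueError(f"unknown feature kind {kind!r}")


_LABEL_RE = re.compile(r"^([JC])(\d+(?:\.\d+)?)R(\d+)$")


def parse_label(label: str):
    """Invert :func:`feature_label`; accepts integer-order forms like J1R756."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable feature label {label!r}")
    prefix, mid, wl = m.groups()
    if prefix == "J":
        return "fracdiff", float(mid), int(wl)
    return "wavelet", int(float(mid)), int(wl)


@dataclass
class SelectedFeature:
    kind: str
    order_or_scale: float | int
    wavelength: float
    rho: float
    p: float
    label: str


@dataclass
class FeatureSelection:
    """Top-k screened features, sorted by |rho| descending, with their
    per-sample value vectors (columns keyed by label)."""

    features: list[SelectedFeature]
    values: pd.DataFrame  # (n_samples, k), columns = labels

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "kind": [f.kind for f in self.features],
                "order_or_scale": [f.order_or_scale for f in self.features],
                "wavelength_nm": [f.wavelength for f in self.features],
                "rho": [f.rho for f in self.features],
                "p": [f.p for f in self.features],
            }
        )


def top_k_features(
    cmap: CorrelationMap,
    source: DerivativeStack | WaveletScalogram,
    k: int = 10,
) -> FeatureSelection:
    """Select the k features with largest |rho| among valid cells.

    Ties in |rho| break deterministically toward the lower wavelength,
    then the lower order/scale.
    """
    rows, cols = np.nonzero(cmap.valid)
    if rows.size < k:
        raise ValueError(f"only {rows.size} valid cells; cannot select top {k}")
    abs_rho = np.abs(cmap.rho[rows, cols])
    order_keys = cmap.row_labels[rows].astype(float)
    idx = np.lexsort((order_keys, cmap.wavelengths[cols], -abs_rho))[:k]
    data = source.data if isinstance(source, DerivativeStack) else source.coefficients
    feats, columns = [], {}
    for j in idx:
        i_row, i_col = rows[j], cols[j]
        label = feature_label(cmap.kind, cmap.row_labels[i_row], cmap.wavelengths[i_col])
        feats.append(
            SelectedFeature(
                cmap.kind,
                float(cmap.row_labels[i_row]) if cmap.kind == "fracdiff" else int(cmap.row_labels[i_row]),
                float(cmap.wavelengths[i_col]),
                float(cmap.rho[i_row, i_col]),
                float(cmap.p[i_row, i_col]),
                label,
            )
        )
        columns[label] = data[i_row, :, i_col]
    return FeatureSelection(feats, pd.DataFrame(columns))
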