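"""Moran's I spatial-autocorrelation diagnostic.

Used to check whether per-country random intercepts from the
hierarchical sleep models cluster geographically. Weights default to
inverse great-circle (haversine) distance, row-standardized with a zero
diagonal; inference is by seeded permutation of the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MoranResult", "morans_i", "haversine_km"]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_units: int
    weight_scheme: str

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "expected_I": self.expected_I,
            "p_value": self.p_value,
            "n_units": self.n_units,
            "weight_scheme": self.weight_scheme,
        }


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix in km."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _weights(
    lat: np.ndarray, lon: np.ndarray, scheme: str, min_distance_km: float
) -> np.ndarray:
    if scheme != "inverse_distance":
        raise ValueError(f"unknown weight_scheme {scheme!r}")
    d = haversine_km(lat, lon)
    # identical coordinates would give infinite weight; floor the distance
    d = np.maximum(d, min_distance_km)
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    row_sums = w.sum(axis=1, keepdims=True)
    return w / row_sums


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    n = z.size
    W = w.sum()
    num = float(z @ w @ z)
    den = float(z @ z)
    return (n / W) * num / den


def morans_i(
    values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    weight_scheme: str = "inverse_distance",
    n_permutations: int = 9999,
    seed: int | None = None,
    min_distance_km: float = 1.0,
) -> MoranResult:
    """Moran's I with a two-sided permutation p-value.

    ``I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with centered
    values z, W the total weight and zero diagonal. The null expectation
    is exactly ``-1/(n-1)``; the p-value is the proportion of
    value-permutations whose |I - E[I]| is at least the observed one
    (add-one correction).
    """
    v = np.asarray(values, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("Moran's I requires at least 3 units")
    if lat.size != n or lon.size != n:
        raise ValueError("values and coordinates must have equal length")
    if np.abs(lat).max() > 90 or np.abs(lon).max() > 180:
        raise ValueError("coordinates out of range")
    if np.std(v) == 0:
        raise ValueError("values are constant; Moran's I is undefined")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    w = _weights(lat, lon, weight_scheme, min_distance_km)
    z = v - v.mean()
    I_obs = _moran_stat(z, w)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    ref = abs(I_obs - expected)
    hits = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        if abs(_moran_stat(zp, w) - expected) >= ref:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MoranResult(
        I=float(I_obs),
        expected_I=float(expected),
        p_value=float(p),
        n_units=int(n),
        weight_scheme=weight_scheme,
    )
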