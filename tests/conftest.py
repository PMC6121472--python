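"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from neuroburst import ElectrodeGeometry, SpikeRaster, SynchronyParams


@pytest.fixture(scope="session")
def geometry() -> ElectrodeGeometry:
    return ElectrodeGeometry()


def brute_force_synchrony(
    raster: SpikeRaster, geometry: ElectrodeGeometry, params: SynchronyParams
) -> np.ndarray:
    """Independent O(n_i * n_j) all-pairs window scan.

    For every ordered pair (i, j) and every spike t_j, loop over every
    spike t_i and count t_j once if any t_i lies in the closed window
    [t_j - tau - delta/2, t_j - tau + delta/2].  Deliberately naive:
    no sorting, no searchsorted — a different code path from the
    implementation it checks.
    """
    n = geometry.n_electrodes
    trains = [raster.times[raster.electrodes == e] for e in range(n)]
    dist = geometry.distance_matrix_um()
    half = params.delta_ms / 2000.0
    C = np.zeros((n, n))
    for j in range(n):
        tj = trains[j]
        if tj.size == 0:
            continue
        for i in range(n):
            if i == j or trains[i].size == 0:
                continue
            tau = dist[i, j] * 1e-6 / params.velocity_m_s
            matched = 0
            for t in tj:
                lo = t - tau - half
                hi = t - tau + half
                for s in trains[i]:
                    if lo <= s <= hi:
                        matched += 1
                        break
            C[i, j] = matched / tj.size
    return C


def random_raster(
    n_spikes: int, n_electrodes: int, duration: float, seed: int
) -> SpikeRaster:
    rng = np.random.default_rng(seed)
    return SpikeRaster(
        electrodes=rng.integers(0, n_electrodes, size=n_spikes),
        times=rng.uniform(0.0, duration, size=n_spikes),
        n_electrodes=n_electrodes,
        duration=duration,
    )
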