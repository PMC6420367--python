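"""Shared fixtures and independent brute-force oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tauroc as tr
from tauroc.synthetic import AV1451_COMPOSITE, PIB_GLOBAL

# Published individual scores for the nine illustrated subjects: two DLB
# extremes and seven PCA patients (occipital composite SUVR).
FIG_DLB = (1.02, 1.42)
FIG_PCA = (3.76, 1.45, 1.31, 3.00, 3.27, 2.72, 2.26)


# --------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# --------------------------------------------------------------------------
def pairwise_auc(positive, negative) -> float:
    """Exhaustive pair counting: P(pos > neg) + ½ P(pos == neg)."""
    wins = 0.0
    for p in positive:
        for n in negative:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(positive) * len(negative))


def flood_fill_components(mask: np.ndarray, connectivity: int = 18) -> list[int]:
    """Connected-component sizes by explicit breadth-first flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    coords = np.argwhere(mask)
    for start in map(tuple, coords):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < mask.shape[0] and 0 <= ny < mask.shape[1]
                        and 0 <= nz < mask.shape[2]
                        and mask[nx, ny, nz] and not seen[nx, ny, nz]):
                    seen[nx, ny, nz] = True
                    stack.append((nx, ny, nz))
        sizes.append(size)
    return sorted(sizes, reverse=True)


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------
@pytest.fixture(scope="session")
def atlas():
    return tr.default_atlas()


@pytest.fixture(scope="session")
def default_spec():
    return tr.table1_cohort_spec()


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return tr.generate_cohort(default_spec, seed=7)


@pytest.fixture(scope="session")
def fig3_table() -> pd.DataFrame:
    rows = [{"subject_id": f"DLB-{i}", "group": "DLB", "occipital_composite": v}
            for i, v in enumerate(FIG_DLB)]
    rows += [{"subject_id": f"PCA-{i}", "group": "PCA", "occipital_composite": v}
             for i, v in enumerate(FIG_PCA)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = tr.default_phantom_spec(noise_sd=0.0)
    return spec, tr.generate_phantom(spec, seed=0)
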