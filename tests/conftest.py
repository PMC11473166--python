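import numpy as np
import pandas as pd
import pytest

import rizmap as rz

#: Analysis settings for single-planted-lesion recovery experiments: the
#: candidate quantile is matched to the expected core fraction (~2% of spots
#: for one r=300 um lesion on a 40x40 lattice).
RECOVERY_Q = 0.96


@pytest.fixture(scope="session")
def square3():
    return rz.generate_lattice(3, 3, "square", 100.0)


@pytest.fixture(scope="session")
def hex3():
    return rz.generate_lattice(3, 3, "hex", 100.0)


@pytest.fixture(scope="session")
def organized_tissue():
    """One organized tissue at the study conditions, shared across tests."""
    return rz.simulate_tissue(seed=1)


@pytest.fixture(scope="session")
def organized_scored(organized_tissue):
    """Normalized matrix, panel scores and observed zones for the shared tissue."""
    adata = rz.normalize(organized_tissue.adata)
    scores = rz.score_panel(adata, organized_tissue.panel, seed=1)
    observed = rz.classify_observed_zone(scores)
    return adata, scores, observed


def run_recovery(seed, condition, n_perm=0):
    """Full pipeline on one synthetic tissue; shared by recovery tests."""
    tissue = rz.simulate_tissue(seed=seed, condition=condition)
    adata = rz.normalize(tissue.adata)
    scores = rz.score_panel(adata, tissue.panel, seed=seed)
    observed = rz.classify_observed_zone(scores)
    lesions = rz.detect_cores(
        tissue.lattice, scores["A"], threshold_quantile=RECOVERY_Q
    )
    if len(lesions) == 0:
        return None
    detected = set(lesions.core_union())
    true_core = set(tissue.truth.core_spot_ids())
    jaccard = len(detected & true_core) / len(detected | true_core)
    expected, _ = rz.expected_zones_from_lesions(tissue.lattice, lesions)
    agreement = rz.agreement_ratio(expected, observed)
    return {
        "tissue": tissue,
        "jaccard": jaccard,
        "agreement": agreement,
        "expected": expected,
        "observed": observed,
    }


def brute_force_components(lattice, subset):
    """Depth-first-search connected components oracle (independent of scipy)."""
    subset = set(subset)
    coords = {sid: (x, y) for sid, x, y in zip(
        lattice.spot_ids, lattice.coords()[:, 0], lattice.coords()[:, 1])}
    r = lattice.neighbor_radius_um()
    comps = []
    remaining = set(subset)
    while remaining:
        start = min(remaining)
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            ux, uy = coords[u]
            for v in remaining:
                if v not in comp:
                    vx, vy = coords[v]
                    if (ux - vx) ** 2 + (uy - vy) ** 2 <= r * r:
                        stack.append(v)
        remaining -= comp
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def brute_force_signed_distance(lattice, core):
    """All-pairs signed-distance oracle."""
    core = set(core)
    xy = lattice.coords()
    ids = list(lattice.spot_ids)
    core_idx = [i for i, s in enumerate(ids) if s in core]
    out_idx = [i for i, s in enumerate(ids) if s not in core]
    d = np.empty(len(ids))
    for i in range(len(ids)):
        pool = out_idx if i in set(core_idx) else core_idx
        dists = [np.hypot(*(xy[i] - xy[j])) for j in pool]
        d[i] = -min(dists) if i in set(core_idx) else min(dists)
    return pd.Series(d, index=lattice.spot_ids)
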