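"""Shared fixtures: schedules, small geometries, and the desk-scale
recovery cohort used by the group-level acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

import mvpakit as m
from mvpakit.behavior import performance
from mvpakit.decoding import DecodingConfig
from mvpakit.searchlight import SphereSpec


@pytest.fixture(scope="session")
def schedule():
    return m.make_schedule(seed=11)


@pytest.fixture(scope="session")
def small_geometry():
    return m.VolumeGeometry(shape=(12, 16, 12))


@pytest.fixture(scope="session")
def recovery_run(small_geometry):
    """Desk-scale parameter-recovery cohort: 12 subjects on a 12x16x12 grid,
    radius-2 searchlight, single SVM cost; returns everything the group-level
    recovery assertions need.  Shared across tests because the decoding pass
    dominates the suite's runtime.
    """
    geom = small_geometry
    regions = m.default_regions(geom)
    sch = m.make_schedule(seed=101)
    bank = m.build_pattern_bank(geom, regions, seed=102)
    profiles = m.sample_cohort(12, (4, 4, 4), seed=103)
    cfg = DecodingConfig(costs=(0.1,))
    spec = SphereSpec(radius=2)
    maps, scores = [], []
    for i, p in enumerate(profiles):
        bs = m.render_beta_series(p, sch, bank, regions, geom,
                                  noise_sd=1.0, seed=200 + i)
        rec = m.simulate_behavior(p, sch, task="category", seed=300 + i)
        scores.append(performance(rec))
        maps.append(m.decode_whole_brain(bs, spec, cfg).data)
    gcfg = m.GroupConfig(n_perm=500, seed=7)
    result = m.run_group_analysis(maps, scores, 0.25, geom.mask, gcfg)
    return {
        "geometry": geom, "regions": regions, "profiles": profiles,
        "scores": scores, "maps": maps, "result": result,
        "sphere_radius": 2,
    }


def region_coverage(mask: np.ndarray, region) -> float:
    return float(mask[tuple(region.voxels.T)].mean())
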