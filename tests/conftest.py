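"""Shared fixtures: small synthetic cohorts and noiseless truths."""

from __future__ import annotations

import dataclasses

import pytest

from fibremech import pipeline, synthetic


def small_cohort_config(seed: int = 7, n_fibers: int = 3) -> synthetic.CohortConfig:
    """Two-group (control vs one-dye) cohort at reduced sizes for fast tests."""
    full = synthetic.paper_trend_cohort(n_fibers=n_fibers, seed=seed)
    groups = tuple(
        dataclasses.replace(g, n_fibers=n_fibers) for g in full.groups[:2]
    )
    return synthetic.CohortConfig(
        groups=groups,
        seed=seed,
        topo_size=(64, 64),
        topo_pixel_size=15.0 / 64.0,
        fd_points=300,
        tensile_points=400,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Generated on disk once per session: (root, manifest, config)."""
    root = tmp_path_factory.mktemp("cohort")
    config = small_cohort_config()
    manifest = synthetic.gen_cohort(config, root)
    return root, manifest, config


@pytest.fixture()
def run_config(small_cohort, tmp_path):
    root, _, _ = small_cohort
    return pipeline.RunConfig(
        dataset_root=str(root), output_dir=str(tmp_path / "out"), seed=7
    )
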