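import numpy as np
import pytest

from ddiconcord.codes import CodeSystem, validate_code
from ddiconcord.cli import PipelineConfig, build_map_artifacts, compare_artifacts
from ddiconcord.synthkb import SynthConfig, generate, write_bundle


def rx(value: str):
    return validate_code(CodeSystem.RXCUI, value)


def db(value: str):
    return validate_code(CodeSystem.DRUGBANK, value)


def zero_noise_config(seed=7, **kw):
    base = dict(
        n_ingredients=50,
        n_drugs=50,
        n_pairs=120,
        n_groups=0,
        inactive_ndc_rate=0.0,
        extra_inactive_link_rate=0.0,
        multi_drugbank_rate=0.0,
        name_mismatch_rate=0.0,
        allergen_rate=0.0,
        salt_suffix_rate=0.0,
        scope_other_rate=0.0,
        symmetric_duplicate_rate=0.0,
        mixed_label_rate=0.0,
    )
    base.update(kw)
    return SynthConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact noisy bundle shared by read-only tests."""
    return generate(SynthConfig(seed=11, n_ingredients=60, n_drugs=72, n_pairs=200))


@pytest.fixture()
def run_pipeline(tmp_path):
    """Write a bundle to disk and run the full pipeline on its files."""

    def _run(bundle, aggregation="max"):
        indir = tmp_path / "in"
        write_bundle(bundle, indir)
        cfg = PipelineConfig(indir, tmp_path / "out", aggregation=aggregation)
        art = build_map_artifacts(cfg)
        return art, compare_artifacts(cfg, art)

    return _run
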