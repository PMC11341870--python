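from __future__ import annotations

import pytest

from kkpscan.simulate import DECOY_CLASSES, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset_factory(tmp_path_factory):
    """Generate (and cache per-config) synthetic datasets for the session."""
    cache = {}

    def make(seed=0, **kwargs):
        key = repr((seed, sorted(kwargs.items(), key=lambda kv: kv[0])))
        skey = str(abs(hash(key)) % 10**8)
        if key not in cache:
            cfg = SynthConfig(seed=seed, **kwargs)
            out = tmp_path_factory.mktemp(f"synth_{skey}")
            cache[key] = generate_dataset(cfg, out)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def small_dataset(dataset_factory):
    """One genome-battery with authentic clusters and every decoy class."""
    return dataset_factory(
        seed=11, n_genomes=6, genes_per_genome=100, n_authentic=8,
        decoy_counts={c: 1 for c in DECOY_CLASSES},
    )
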