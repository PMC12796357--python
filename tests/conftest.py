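import warnings

import numpy as np
import pandas as pd
import pytest

from pidscape import background_model as bg
from pidscape import synthetic_data as synth
from pidscape.contact_store import BinnedContacts, merge_replicates, scale_to_smallest
from pidscape.genome import GenomeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_random_contacts(layout, rng, density=0.1, label=""):
    """Random upper-triangle matrix for structural tests."""
    m = BinnedContacts(layout, label=label)
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        iu, ju = np.triu_indices(n)
        keep = rng.random(iu.size) < density
        counts = rng.integers(1, 20, size=keep.sum()).astype(float)
        m.set_chrom(chrom, iu[keep], ju[keep], counts)
    return m


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("chr1",), (20_000,), 1000)


def promoters_of(genes, halfwidth=2500):
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["start"] - halfwidth).clip(lower=0),
            "end": genes["start"] + halfwidth,
        }
    )


class ToyStack:
    """A small but full simulate -> background -> merged-matrix stack shared
    across module tests (session scope: built once)."""

    def __init__(self, seed=3):
        self.seed = seed
        self.config = synth.SimConfig(seed=seed, target_depth=300_000.0)
        self.layout, self.genes, self.cres, _ = synth.make_genome(
            self.config, 12, 40, chrom_length=5_000_000
        )
        self.loops, self.anchor_cres = synth.plant_loops(
            self.layout, self.genes, 6, base_enhancement=4.0, seed=seed
        )
        self.all_cres = pd.concat(
            [self.cres[["chrom", "start", "end", "name"]], self.anchor_cres],
            ignore_index=True,
        )
        self.mask = synth.build_inactive_mask(
            self.layout,
            [
                self.genes[["chrom", "start", "end"]],
                promoters_of(self.genes),
                self.all_cres,
            ],
        )
        self.replicates = synth.simulate_contacts(
            self.layout, self.loops, self.config, condition="a"
        )
        self.merged = merge_replicates(scale_to_smallest(self.replicates))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = bg.sample_background_regions(
                self.layout, self.mask, n=1500, seed=seed
            )
        self.model = bg.flatten_far_field(bg.fit_background(self.merged, regions))


@pytest.fixture(scope="session")
def toy_stack():
    return ToyStack()
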