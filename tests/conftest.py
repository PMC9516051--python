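"""Shared fixtures: a small synthetic world reused across module tests."""

import numpy as np
import pandas as pd
import pytest

from demether import methylome, simulate


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimConfig:
    """Desk-scale-but-small configuration: 2 x 300 kb chromosomes + scaffold."""
    return simulate.SimConfig(
        seed=11,
        genome=simulate.GenomePlan(
            chrom_lengths=(("chr1", 300_000), ("chr2", 300_000), ("scaffold_282", 60_000))
        ),
        annotation=simulate.AnnotationPlan(
            n_genes=30,
            n_helitrons=25,
            n_gypsies=12,
            n_tandem=6,
            n_trna=8,
            n_mirna=4,
            n_5s=4,
            n_nor=1,
            nor_length=2_000,
        ),
        dmr=simulate.DmrPlan(n_dmrs=40, n_chh_regions=25),
        sirna=simulate.SirnaPlan(background_loci=300),
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Annotation, planted regions, and replicate methylomes for the small genome."""
    rng = small_cfg.rng()
    ann = simulate.make_genome_annotation(small_cfg, rng)
    planted = simulate.plant_regions(small_cfg, ann, rng)
    maps = simulate.simulate_methylomes(small_cfg, ann, planted, rng)
    return {"cfg": small_cfg, "annotation": ann, "planted": planted, "maps": maps}


@pytest.fixture(scope="session")
def merged_pair(small_world):
    """Merged mutant/wild-type endosperm maps and their CG/CHG paired tables."""
    maps = small_world["maps"]
    mut = methylome.merge_replicates(maps["mut_endosperm"], "mut")
    wt = methylome.merge_replicates(maps["wt_endosperm"], "wt")
    return {
        "mut": mut,
        "wt": wt,
        "cg": methylome.intersect_samples(mut, wt, "CG"),
        "chg": methylome.intersect_samples(mut, wt, "CHG"),
    }


def random_intervals(rng: np.random.Generator, n: int, span: int = 10_000,
                     max_len: int = 400, chroms=("chr1", "chr2")) -> pd.DataFrame:
    """Random interval set for oracle comparisons."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
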