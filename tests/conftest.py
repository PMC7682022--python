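import numpy as np
import pytest

from prsvar.config import RunConfig
from prsvar.containers import default_variant_table, merge_panels
from prsvar.emulator import EmulatorConfig, emulate_hmm
from prsvar import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small two-population simulated dataset shared across test modules."""
    n_var = 60
    variants = default_variant_table(n_var)
    anc = sim.draw_ancestral_frequencies(n_var, (0.05, 0.5), rng_seed=11)
    fa = sim.derive_population_frequencies(anc, 0.0, rng_seed=12, label="EUR")
    fb = sim.derive_population_frequencies(anc, 0.15, rng_seed=13, label="AFR")
    pa = sim.simulate_haplotype_panel(fa, 80, 10, rng_seed=14, variants=variants)
    pb = sim.simulate_haplotype_panel(fb, 80, 10, rng_seed=15, variants=variants)
    panel = merge_panels([pa, pb])
    cohort = sim.simulate_cohort(panel, {"EUR": 80, "AFR": 40}, rng_seed=16)
    model = sim.generate_prs_model(variants=variants, rng_seed=17, n_high_weight=2)
    mask = sim.assign_typed_mask(n_var, 0.3, rng_seed=18)
    return {"panel": panel, "cohort": cohort, "model": model, "mask": mask}


@pytest.fixture(scope="session")
def small_replicates(small_sim):
    cfg = EmulatorConfig(mode="hmm", k=6)
    return emulate_hmm(
        small_sim["cohort"],
        small_sim["mask"],
        small_sim["panel"],
        cfg,
        mode="sampled",
        master_seed=19,
    )


@pytest.fixture()
def tiny_config(tmp_path):
    """A pipeline configuration small enough for sub-second end-to-end runs."""
    return RunConfig(
        master_seed=5,
        populations={"EUR": 40, "AFR": 20},
        fst={"EUR": 0.0, "AFR": 0.15},
        n_variants=40,
        panel_haplotypes_per_population=40,
        block_length=8,
        fraction_typed=0.3,
        k=3,
    )
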