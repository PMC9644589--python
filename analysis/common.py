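"""Shared paths and cohort layout for the numbered analysis drivers.

The simulated cohort: 4 lentiviral + 4 γ-retroviral junction libraries over
one shared 3 × 300 kb reference, 300 planted sites per product. Bulky
intermediates (FASTQ, FASTA) live under scratch/; result tables under
results/cohort/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "cohort"

BASE_SEED = 1
N_LENTI = 4
N_RETRO = 4
N_SITES = 300
READS_PER_SITE = 25


def base_config(seed: int = BASE_SEED):
    from iskit.simjunction import SimConfig

    return SimConfig(seed=seed, n_sites=N_SITES, reads_per_site=READS_PER_SITE)


def sample_plan(seed: int = BASE_SEED):
    from iskit.simjunction import cohort_configs

    return cohort_configs(base_config(seed), N_LENTI, N_RETRO)
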