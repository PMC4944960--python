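import numpy as np
import pytest
from hypothesis import settings

from mitomosaic.borotoy import borotoy_config
from mitomosaic.pipeline import run_pipeline
from mitomosaic.resolve import order_string

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

N_SEEDS = 20


@pytest.fixture(scope="session")
def borotoy_result():
    """One full BoroToy pipeline run (fixed seed), shared across tests."""
    return run_pipeline(borotoy_config(seed=11))


@pytest.fixture(scope="session")
def borotoy_rundir(tmp_path_factory):
    """A full run with all artifacts written to disk."""
    outdir = tmp_path_factory.mktemp("borotoy_run")
    result = run_pipeline(borotoy_config(seed=7), outdir=outdir)
    return outdir, result


@pytest.fixture(scope="session")
def borotoy_multiseed():
    """Reduced per-seed records of full pipeline runs over N_SEEDS seeds,
    used by the structure round-trip, copy-number recovery and ORF-screen
    recovery suites."""
    records = []
    for seed in range(N_SEEDS):
        res = run_pipeline(borotoy_config(seed=seed),
                           primer_pairs=[], enzyme=None)
        truth = res.truth
        spec = [r for r in res.orfs if r.classification == "specific"]
        records.append({
            "seed": seed,
            "found_orders": sorted(order_string(c.order)
                                   for c in res.structure.circles),
            "truth_orders": sorted(order_string(c.order)
                                   for c in truth.genome.circles),
            "copy_estimate": dict(res.graph.copy_estimate),
            "substoich": set(res.graph.substoichiometric),
            "specific_seqs": {r.seq for r in spec},
            "planted_seqs": {o.seq for o in truth.planted},
            "chimeric_lengths": sorted(r.peptide_length for r in spec
                                       if r.is_chimeric),
            "chimera_donors": {r.peptide_length: [h.donor for h in r.chimera_hits]
                               for r in spec if r.is_chimeric},
            "abundance_ratio": res.abundance[0].ratio if res.abundance else None,
            "repeat_lengths": [h.match.length
                               for h in res.structure.master_hypotheses],
            "subgenome_count": len(res.structure.subgenomes),
        })
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(0)
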