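import numpy as np
import pandas as pd
import pytest

from cottonsnp.simulate import SimulationConfig, simulate_reference
from cottonsnp.sites import PILEUP_COLUMNS


def make_pileup(rows):
    """Build a pileup frame from (contig, pos, ref, counts-dict, indel) tuples."""
    recs = []
    for contig, pos, ref, counts, indel in rows:
        rec = {"contig": contig, "pos": pos, "ref": ref,
               "depth": sum(counts.values()), "indel": indel}
        for b in "ACGT":
            rec[b] = counts.get(b, 0)
        recs.append(rec)
    return pd.DataFrame(recs)[PILEUP_COLUMNS]


def random_pileup(rng, n_sites, n_contigs=3, indel_rate=0.1):
    """A random pileup frame with a mix of depths, alleles and indel flags."""
    bases = np.array(list("ACGT"))
    recs = []
    for i in range(n_sites):
        c = f"c{rng.integers(n_contigs)}"
        ref = str(bases[rng.integers(4)])
        depth = int(rng.integers(0, 40))
        counts = {b: 0 for b in "ACGT"}
        if depth:
            main = str(bases[rng.integers(4)])
            n_main = int(rng.integers(depth // 2, depth + 1))
            counts[main] = n_main
            rest = depth - n_main
            for _ in range(rest):
                counts[str(bases[rng.integers(4)])] += 1
        recs.append((c, i + 1, ref, counts, bool(rng.random() < indel_rate)))
    return make_pileup(recs)


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated world shared by read-only tests."""
    config = SimulationConfig(n_contigs=12, contig_length_mean=500,
                              contig_length_sd=80, seed=7)
    contigs, truth = simulate_reference(config)
    return config, contigs, truth
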