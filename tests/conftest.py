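import numpy as np
import pandas as pd
import pytest

from hybzone.io_anchor import GenotypeMatrix


def make_matrix(dosage, scaffolds=None, positions=None, qual=None, gq=None, dp=None):
    """GenotypeMatrix from a dosage array with auto-generated coordinates."""
    dosage = np.asarray(dosage, dtype=float)
    n, L = dosage.shape
    loci = pd.DataFrame(
        {
            "scaffold": scaffolds if scaffolds is not None else ["chr1"] * L,
            "pos": positions if positions is not None else 100 * (np.arange(L) + 1),
            "ref": "A",
            "alt": "G",
            "qual": qual if qual is not None else 999.0,
        }
    )
    samples = [f"s{i:03d}" for i in range(n)]
    return GenotypeMatrix(dosage, samples, loci, gq=gq, dp=dp)


@pytest.fixture(scope="session")
def small_zone():
    """A latitudinal hybrid zone small enough for unit tests (cached per session)."""
    from hybzone import sim

    cfg = sim.SimConfig(
        n_individuals=150,
        n_loci=300,
        n_scaffolds=15,
        loci_per_scaffold=20,
        divergence_F=0.3,
        missing_rate=0.05,
        seed=42,
    )
    matrix, frame, truth, env = sim.simulate_hybrid_zone(cfg)
    return {"config": cfg, "matrix": matrix, "frame": frame, "truth": truth, "env": env}
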