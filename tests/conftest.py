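import textwrap

import numpy as np
import pytest

from designvar.msa_io import Alignment, CountMatrix, build_site_map, column_counts
from designvar.synthetic_data import SyntheticSpec, generate_design_alignment, generate_natural_alignment, sample_rsa_profile


@pytest.fixture
def tiny_alignment() -> Alignment:
    """3 sequences x 10 columns, reference gapped at column 4."""
    return Alignment(
        [
            ("ref", "ACDE-FGHIK"),
            ("s1", "ACDEEFGHIK"),
            ("s2", "AC-ELFGHIX"),
        ],
        reference_id="ref",
        source_label="natural",
    )


@pytest.fixture
def tiny_counts(tiny_alignment) -> CountMatrix:
    smap = build_site_map(tiny_alignment)
    return column_counts(tiny_alignment, smap)


def dssp_text(residues, chain="A", extra_chain=None) -> str:
    """Render classic DSSP output for (aa, acc) residue tuples."""
    header = textwrap.dedent(
        """\
        ==== SECONDARY STRUCTURE DEFINITION BY THE PROGRAM DSSP, CMBI VERSION ====
        REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637
        HEADER    SYNTHETIC TEST STRUCTURE
          #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
        """
    )
    lines = []
    serial = 0
    for ch, res in [(chain, residues)] + ([(extra_chain[0], extra_chain[1])] if extra_chain else []):
        for i, (aa, acc) in enumerate(res, start=1):
            serial += 1
            prefix = f"{serial:5d}{i:5d} {ch} {aa}"
            line = prefix + " " * (34 - len(prefix)) + f"{acc:4d}"
            lines.append(line)
    return header + "\n".join(lines) + "\n"


@pytest.fixture
def dssp_file(tmp_path):
    """Classic DSSP fixture: 3 chain-A residues with ACC 0, 55, 120."""
    path = tmp_path / "test.dssp"
    path.write_text(dssp_text([("M", 0), ("K", 55), ("L", 120)]))
    return path


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic protein: RSA profile, natural + designed alignments.

    Session-scoped because several modules exercise the same scenario.
    """
    spec = SyntheticSpec(seed=11)
    rsa = sample_rsa_profile(spec)
    natural, truth = generate_natural_alignment(spec, rsa)
    designs = {}
    for T in spec.temperatures:
        aln, t_truth = generate_design_alignment(spec, rsa, T)
        designs[T] = aln
        truth.design_dists[T] = t_truth.design_dists[T]
    return {"spec": spec, "rsa": rsa, "natural": natural, "designs": designs, "truth": truth}


def random_pseudocounted_profiles(rng: np.random.Generator, n_sites: int, n_seqs: int = 20):
    """Random count matrices -> pseudocounted frequency pair (p, q)."""
    from designvar.site_statistics import site_frequencies

    def one():
        counts = rng.multinomial(n_seqs, rng.dirichlet(np.ones(20) * 0.5), size=n_sites)
        cm = CountMatrix(counts, counts.sum(axis=1), np.arange(1, n_sites + 1))
        return site_frequencies(cm, pseudocount=True)

    return one(), one()
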