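"""Hybrid design alignments: core columns from one design condition, surface
columns from another.

A hybrid takes each buried or partially-buried alignment column from the
"core" condition and each exposed column from the "surface" condition, per
the three-class RSA scheme on the native structure. Hybrids are an
illustration of how much more variable surface sites must be relative to core
sites to reproduce natural entropy-RSA correlations; they carry no claim of
being designable or stable sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa_io import Alignment, SiteMap, build_site_map, column_counts
from .site_statistics import site_entropy, site_frequencies
from .solvent_accessibility import (
    BURIED,
    EXPOSED,
    PARTIAL,
    ExposureScheme,
    RSAProfile,
    THREE_CLASS,
    classify_exposure,
)
from .exposure_analysis import CorrelationResult, entropy_rsa_correlation, join_site_table


@dataclass(frozen=True)
class HybridRecipe:
    """Which condition supplies core (buried + partially buried) vs surface columns."""

    core_condition: str
    surface_condition: str
    scheme: ExposureScheme = THREE_CLASS

    def __post_init__(self) -> None:
        if self.scheme.scheme_name != "three_class":
            raise ValueError("hybrid construction requires the three-class scheme")


def build_hybrid(
    core: Alignment,
    surface: Alignment,
    site_map: SiteMap,
    rsa: RSAProfile,
    recipe: HybridRecipe,
) -> Alignment:
    """Splice core-condition and surface-condition columns into one alignment.

    Row k of the hybrid concatenates columns from row k of each source, so the
    output is a well-formed alignment; columnwise statistics are unaffected by
    this pairing choice. Columns outside the site map (reference-gapped) are
    taken from the core source so sequence lengths are preserved.
    """
    if core.length != surface.length:
        raise ValueError("core and surface alignments differ in aligned length")
    if core.n_records != surface.n_records:
        raise ValueError("core and surface alignments differ in record count")
    rsa_map = rsa.rsa_by_position()
    use_surface = np.zeros(core.length, dtype=bool)
    for col, pos in site_map.pairs:
        if pos not in rsa_map:
            raise ValueError(f"structure position {pos} missing from RSA profile")
        cls = classify_exposure(rsa_map[pos], recipe.scheme)
        use_surface[col] = cls == EXPOSED
    records = []
    for k, ((cid, cseq), (_sid, sseq)) in enumerate(zip(core.records, surface.records)):
        hybrid_seq = "".join(
            sseq[i] if use_surface[i] else cseq[i] for i in range(core.length)
        )
        records.append((f"hybrid_{k}", hybrid_seq))
    # keep the core reference row's position in the record list as reference
    ref_index = next(
        i for i, (rid, _s) in enumerate(core.records) if rid == core.reference_id
    )
    ref_id = records[ref_index][0]
    return Alignment(
        records,
        reference_id=ref_id,
        source_label="hybrid",
        condition=f"{recipe.core_condition}+{recipe.surface_condition}",
    )


def hybrid_correlation_analysis(
    hybrid: Alignment,
    natural: Alignment,
    site_map: SiteMap,
    rsa: RSAProfile,
    method: str = "pearson",
    protein_id: str = "",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Entropy-RSA correlation for the hybrid set and the natural set, paired."""
    results = []
    for aln, tag in ((hybrid, "hybrid"), (natural, "natural")):
        counts = column_counts(aln, site_map)
        ev = site_entropy(site_frequencies(counts, pseudocount=False))
        table = join_site_table({tag: ev}, counts.positions, rsa)
        results.append(
            entropy_rsa_correlation(table, tag, method=method, protein_id=protein_id)
        )
    return results[0], results[1]
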