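"""End-to-end orchestration: config validation, per-protein analysis, reports.

A run is described by one declarative YAML config listing, per protein, the
natural alignment, any number of designed alignments keyed by condition tag,
and the accessibility source (a DSSP file + chain, or a precomputed RSA
table), plus analysis options. The pipeline computes, for every protein and
condition: mean site entropy, mean KL and rank-ordered KL divergence against
the natural reference, the entropy-RSA correlation, and the natural
split-half control; then pools exposure-class entropy and amino-acid
frequency tables across proteins and summarises distributions per condition.

Failures are isolated per protein: one unreadable input marks that protein
failed in ``failures.tsv`` without aborting the rest of the run. Outputs are
deterministic given inputs, config and seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .msa_io import Alignment, build_site_map, column_counts, read_alignment
from .site_statistics import (
    kl_divergence,
    mean_entropy,
    per_protein_mean,
    rank_ordered_kl,
    site_entropy,
    site_frequencies,
    split_half_control,
)
from .solvent_accessibility import (
    ExposureScheme,
    compute_rsa,
    parse_dssp,
    read_rsa_table,
)
from .exposure_analysis import (
    class_aa_frequencies,
    class_entropy_by_protein,
    class_entropy_summary,
    entropy_rsa_correlation,
    join_site_table,
    summarize_conditions,
)
from .hybrid_designs import HybridRecipe, build_hybrid, hybrid_correlation_analysis
from .solvent_accessibility import TWO_CLASS

logger = logging.getLogger(__name__)

_OPTION_DEFAULTS = {
    "correlation_method": "pearson",
    "pseudocount_entropy": False,  # the pseudocount is a KL-only device by default
    "exposure_scheme": "three_class",
    "buried_max": 0.05,
    "partial_max": 0.25,
    "control_seed": 0,
    "control_reps": 1,
    "max_asa_table": "tien2013",
}

_PROTEIN_KEYS = {"id", "natural", "reference_id", "designs", "dssp", "chain", "rsa_table"}


@dataclass
class ProteinEntry:
    protein_id: str
    natural: Path
    designs: dict[str, Path]
    reference_id: str = "first"
    dssp: Path | None = None
    chain: str | None = None
    rsa_table: Path | None = None


@dataclass
class RunConfig:
    proteins: list[ProteinEntry]
    output_dir: Path
    options: dict = field(default_factory=lambda: dict(_OPTION_DEFAULTS))
    hybrids: list[dict] = field(default_factory=list)

    @property
    def exposure_scheme(self) -> ExposureScheme:
        return ExposureScheme(
            self.options["exposure_scheme"],
            self.options["buried_max"],
            self.options["partial_max"],
        )


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, filling option defaults.

    Unknown keys raise (no silent typos); every referenced path must exist;
    exposure thresholds must be ordered.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    allowed_top = {"proteins", "output_dir", "options", "hybrids"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "output_dir" not in raw:
        raise ValueError("config must set output_dir")
    base = Path(path).parent

    options = dict(_OPTION_DEFAULTS)
    for k, v in (raw.get("options") or {}).items():
        if k not in _OPTION_DEFAULTS:
            raise ValueError(f"unknown option key: {k!r}")
        options[k] = v
    if not (0 < options["buried_max"] < options["partial_max"] < 1):
        raise ValueError("need 0 < buried_max < partial_max < 1")

    entries = []
    for i, p in enumerate(raw.get("proteins") or []):
        unknown = set(p) - _PROTEIN_KEYS
        if unknown:
            raise ValueError(f"unknown protein keys: {sorted(unknown)}")
        if "natural" not in p:
            raise ValueError(f"protein entry {i} missing 'natural'")
        if ("rsa_table" in p) == ("dssp" in p):
            raise ValueError(
                f"protein entry {i}: exactly one of rsa_table or dssp is required"
            )
        if "dssp" in p and "chain" not in p:
            raise ValueError(f"protein entry {i}: dssp requires a chain")

        def resolve(key):
            return (base / p[key]).resolve() if key in p else None

        entry = ProteinEntry(
            protein_id=str(p.get("id", f"protein_{i}")),
            natural=resolve("natural"),
            designs={
                str(tag): (base / rel).resolve()
                for tag, rel in (p.get("designs") or {}).items()
            },
            reference_id=str(p.get("reference_id", "first")),
            dssp=resolve("dssp"),
            chain=p.get("chain"),
            rsa_table=resolve("rsa_table"),
        )
        if len(entry.designs) != len(set(entry.designs)):
            raise ValueError("condition tags must be unique per protein")
        for f in [entry.natural, entry.dssp, entry.rsa_table, *entry.designs.values()]:
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"config references missing file: {f}")
        entries.append(entry)
    if not entries:
        raise ValueError("config lists no proteins")

    hybrids = []
    for h in raw.get("hybrids") or []:
        unknown = set(h) - {"core", "surface"}
        if unknown:
            raise ValueError(f"unknown hybrid keys: {sorted(unknown)}")
        hybrids.append({"core": str(h["core"]), "surface": str(h["surface"])})

    return RunConfig(
        proteins=entries,
        output_dir=(base / raw["output_dir"]).resolve(),
        options=options,
        hybrids=hybrids,
    )


def _load_rsa(entry: ProteinEntry, options: dict):
    if entry.rsa_table is not None:
        return read_rsa_table(entry.rsa_table)
    profile = parse_dssp(entry.dssp, entry.chain)
    return compute_rsa(profile, options["max_asa_table"])


def _analyze_protein(entry: ProteinEntry, config: RunConfig):
    """All per-protein statistics; returns (per-protein rows, site table, class frame)."""
    opts = config.options
    scheme = config.exposure_scheme
    natural = read_alignment(entry.natural, entry.reference_id, source_label="natural")
    site_map = build_site_map(natural)
    rsa = _load_rsa(entry, opts)

    nat_counts = column_counts(natural, site_map)
    nat_H = site_entropy(
        site_frequencies(nat_counts, pseudocount=opts["pseudocount_entropy"])
    )
    q = site_frequencies(nat_counts, pseudocount=True)

    controls = [
        split_half_control(natural, site_map, seed=int(opts["control_seed"]) + rep)
        for rep in range(int(opts["control_reps"]))
    ]
    control_kl = float(np.mean(controls))

    entropies = {"natural": nat_H}
    divergences = {}
    rows = []
    conditions = ["natural"]
    alignments = {"natural": natural}
    for tag, path in entry.designs.items():
        aln = read_alignment(path, "first", source_label="designed", condition=tag)
        if aln.length != natural.length:
            raise ValueError(
                f"designed alignment {tag!r} length {aln.length} != natural {natural.length}"
            )
        counts = column_counts(aln, site_map)
        H = site_entropy(site_frequencies(counts, pseudocount=opts["pseudocount_entropy"]))
        p = site_frequencies(counts, pseudocount=True)
        entropies[tag] = H
        divergences[f"kl_{tag}"] = kl_divergence(p, q).values
        divergences[f"rank_kl_{tag}"] = rank_ordered_kl(p, q).values
        conditions.append(tag)
        alignments[tag] = aln

    table = join_site_table(entropies, nat_counts.positions, rsa, scheme, divergences)
    method = opts["correlation_method"]

    for tag in conditions:
        row = {
            "protein_id": entry.protein_id,
            "condition": tag,
            "mean_entropy": mean_entropy(entropies[tag]),
            "split_half_control_kl": control_kl if tag == "natural" else np.nan,
        }
        if tag != "natural":
            row["mean_kl"] = float(np.mean(divergences[f"kl_{tag}"]))
            row["mean_rank_kl"] = float(np.mean(divergences[f"rank_kl_{tag}"]))
        else:
            row["mean_kl"] = np.nan
            row["mean_rank_kl"] = np.nan
        try:
            row["entropy_rsa_r"] = entropy_rsa_correlation(
                table, tag, method=method, protein_id=entry.protein_id
            ).coefficient
        except ValueError:
            row["entropy_rsa_r"] = np.nan  # undefined, reported as missing
        rows.append(row)

    class_frame = class_entropy_by_protein(table, conditions, scheme)
    class_frame.insert(0, "protein_id", entry.protein_id)

    hybrid_rows = []
    for recipe_dict in config.hybrids:
        core_tag, surf_tag = recipe_dict["core"], recipe_dict["surface"]
        if core_tag not in alignments or surf_tag not in alignments:
            raise ValueError(
                f"hybrid recipe references unknown conditions {core_tag!r}/{surf_tag!r}"
            )
        recipe = HybridRecipe(core_tag, surf_tag)
        hybrid = build_hybrid(
            alignments[core_tag], alignments[surf_tag], site_map, rsa, recipe
        )
        h_res, n_res = hybrid_correlation_analysis(
            hybrid, natural, site_map, rsa, method=method, protein_id=entry.protein_id
        )
        hybrid_rows.append(
            {
                "protein_id": entry.protein_id,
                "core": core_tag,
                "surface": surf_tag,
                "hybrid_r": h_res.coefficient,
                "natural_r": n_res.coefficient,
            }
        )

    return rows, table, class_frame, hybrid_rows, (natural, site_map, rsa)


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline; write TSV reports and return them in memory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("designvar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("designvar %s starting run with %d proteins", __version__, len(config.proteins))

    per_protein_rows: list[dict] = []
    class_frames: list[pd.DataFrame] = []
    hybrid_rows: list[dict] = []
    failures: list[dict] = []
    joined = {"alignments": [], "maps": [], "rsa": []}

    for entry in config.proteins:
        try:
            rows, table, class_frame, h_rows, (nat, smap, rsa) = _analyze_protein(
                entry, config
            )
        except Exception as exc:  # per-protein isolation
            logger.exception("protein %s failed", entry.protein_id)
            failures.append({"protein_id": entry.protein_id, "error": str(exc)})
            continue
        per_protein_rows.extend(rows)
        class_frames.append(class_frame)
        hybrid_rows.extend(h_rows)
        joined["alignments"].append(nat)
        joined["maps"].append(smap)
        joined["rsa"].append(rsa)
        table.to_csv(
            out / f"sites_{entry.protein_id}.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )

    if not per_protein_rows:
        raise RuntimeError("every protein failed; see failures.tsv and run.log")

    reports: dict[str, pd.DataFrame] = {}
    reports["per_protein"] = pd.DataFrame(per_protein_rows)
    reports["condition_summary"] = summarize_conditions(reports["per_protein"])
    reports["class_entropy"] = class_entropy_summary(class_frames)
    reports["class_frequencies"] = class_aa_frequencies(
        joined["alignments"], joined["maps"], joined["rsa"], TWO_CLASS
    )
    reports["correlations"] = reports["per_protein"][
        ["protein_id", "condition", "entropy_rsa_r"]
    ].copy()
    if hybrid_rows:
        reports["hybrids"] = pd.DataFrame(hybrid_rows)
    reports["failures"] = pd.DataFrame(failures, columns=["protein_id", "error"])

    name_map = {
        "per_protein": "per_protein.tsv",
        "condition_summary": "condition_summary.tsv",
        "class_entropy": "class_entropy.tsv",
        "class_frequencies": "class_frequencies.tsv",
        "correlations": "correlations.tsv",
        "hybrids": "hybrids.tsv",
        "failures": "failures.tsv",
    }
    for key, frame in reports.items():
        frame.to_csv(out / name_map[key], sep="\t", index=False, float_format="%.6f")
    logger.info(
        "run complete: %d proteins analyzed, %d failed",
        len(class_frames),
        len(failures),
    )
    root.removeHandler(handler)
    handler.close()
    return reports
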