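"""Relative solvent accessibility (RSA) from DSSP output, and exposure classes.

DSSP reports the absolute solvent-accessible surface area (ASA, in Å²) of each
residue in its ACC column. RSA is the ASA divided by the residue's maximum
possible ASA; the default normalisation uses the theoretical maxima of
Tien et al. (2013), with the older Miller et al. (1987) empirical scale
available as an alternative. Residues are classified into exposure classes:

* three_class: buried (RSA <= 0.05), partially buried (0.05 < RSA <= 0.25),
  exposed (RSA > 0.25) — used for class-wise entropy summaries and hybrids.
* two_class: buried (RSA <= 0.05) vs exposed (RSA > 0.05) — used for
  exposure-stratified amino-acid frequency tables.

RSA is computed on the native structure only; designed sequences inherit the
native profile by structure position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Theoretical maximum ASA per residue (Å²), Tien et al. 2013.
MAX_ASA_TIEN_2013 = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Empirical maximum ASA per residue (Å²), Miller et al. 1987.
MAX_ASA_MILLER_1987 = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "E": 183.0, "Q": 189.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

MAX_ASA_TABLES = {
    "tien2013": MAX_ASA_TIEN_2013,
    "miller1987": MAX_ASA_MILLER_1987,
}

BURIED = "buried"
PARTIAL = "partially_buried"
EXPOSED = "exposed"


@dataclass
class RSAProfile:
    """Per-residue accessibility on the native structure.

    ``residues`` holds ``(structure_position, aa, asa, rsa)`` tuples with
    strictly increasing 1-based positions. ``rsa`` may be ``None`` until
    :func:`compute_rsa` fills it.
    """

    residues: list[tuple[int, str, float | None, float | None]]

    def __post_init__(self) -> None:
        positions = [p for p, *_ in self.residues]
        if positions != sorted(set(positions)):
            raise ValueError("positions must be strictly increasing and unique")
        for pos, aa, asa, rsa in self.residues:
            if asa is not None and asa < 0:
                raise ValueError(f"negative ASA at position {pos}")
            if rsa is not None and rsa < 0:
                raise ValueError(f"negative RSA at position {pos}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        return [p for p, *_ in self.residues]

    def rsa_by_position(self) -> dict[int, float]:
        out = {}
        for pos, _aa, _asa, rsa in self.residues:
            if rsa is None:
                raise ValueError("RSA not computed yet; call compute_rsa first")
            out[pos] = rsa
        return out


@dataclass(frozen=True)
class ExposureScheme:
    """Named RSA-threshold scheme partitioning [0, inf) into exposure classes."""

    scheme_name: str = "three_class"  # or "two_class"
    buried_max: float = 0.05
    partial_max: float = 0.25

    def __post_init__(self) -> None:
        if self.scheme_name not in ("three_class", "two_class"):
            raise ValueError(f"unknown scheme {self.scheme_name!r}")
        if not (0 < self.buried_max < 1):
            raise ValueError("buried_max must lie in (0, 1)")
        if self.scheme_name == "three_class" and not (
            self.buried_max < self.partial_max < 1
        ):
            raise ValueError("need buried_max < partial_max < 1")

    @property
    def classes(self) -> tuple[str, ...]:
        if self.scheme_name == "three_class":
            return (BURIED, PARTIAL, EXPOSED)
        return (BURIED, EXPOSED)


THREE_CLASS = ExposureScheme("three_class")
TWO_CLASS = ExposureScheme("two_class")


def classify_exposure(rsa: float, scheme: ExposureScheme = THREE_CLASS) -> str:
    """Assign an RSA value to its exposure class (boundaries inclusive below)."""
    if rsa < 0:
        raise ValueError("RSA must be nonnegative")
    if rsa <= scheme.buried_max:
        return BURIED
    if scheme.scheme_name == "two_class":
        return EXPOSED
    if rsa <= scheme.partial_max:
        return PARTIAL
    return EXPOSED


def parse_dssp(path, chain: str) -> RSAProfile:
    """Parse classic fixed-column DSSP output for one chain.

    Extracts the ACC (ASA) field per residue of the requested chain,
    renumbering residues 1..n in order of appearance. Chain-break lines
    (``!`` in the AA column) and lines for other chains are skipped. RSA is
    left unset; fill it with :func:`compute_rsa`. mmCIF-style DSSP output is
    rejected.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"empty DSSP file: {path}")
    if lines[0].lstrip().startswith(("data_", "#")):
        raise ValueError(f"{path} looks like mmCIF-style DSSP output; classic format required")
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("  #  RESIDUE"):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"missing DSSP residue-table header in {path}")

    residues: list[tuple[int, str, float | None, float | None]] = []
    seen_chains: set[str] = set()
    n_skipped = 0
    pos = 0
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if len(line) < 38:
            continue
        aa = line[13]
        if aa == "!":  # chain break / discontinuity
            n_skipped += 1
            continue
        line_chain = line[11]
        seen_chains.add(line_chain)
        if line_chain != chain:
            continue
        if aa.islower():  # DSSP lowercases cysteines in disulfide bridges
            aa = "C"
        acc_text = line[34:38].strip()
        try:
            asa = float(acc_text)
        except ValueError:
            raise ValueError(
                f"non-numeric ACC field {acc_text!r} at line {lineno} of {path}"
            ) from None
        pos += 1
        residues.append((pos, aa, asa, None))
    if not residues:
        available = ", ".join(sorted(seen_chains)) or "(none)"
        raise ValueError(
            f"chain {chain!r} not found in {path}; available chains: {available}"
        )
    if n_skipped:
        logger.info("%d chain-break/missing lines skipped in %s", n_skipped, path)
    return RSAProfile(residues)


def compute_rsa(profile: RSAProfile, max_asa_table: dict[str, float] | str = "tien2013") -> RSAProfile:
    """Fill RSA = ASA / max_ASA(residue) for every residue of the profile.

    Values above 1 (possible under theoretical max-ASA scales) are retained,
    not clipped, and counted in a log warning.
    """
    if isinstance(max_asa_table, str):
        max_asa_table = MAX_ASA_TABLES[max_asa_table]
    out = []
    n_above_one = 0
    for pos, aa, asa, _rsa in profile.residues:
        if aa not in max_asa_table:
            raise ValueError(f"residue {aa!r} at position {pos} missing from max-ASA table")
        if asa is None:
            raise ValueError(f"ASA missing at position {pos}")
        rsa = asa / max_asa_table[aa]
        if rsa > 1:
            n_above_one += 1
        out.append((pos, aa, asa, rsa))
    if n_above_one:
        logger.warning("%d residues have RSA > 1 (kept unclipped)", n_above_one)
    return RSAProfile(out)


def read_rsa_table(path) -> RSAProfile:
    """Read a precomputed RSA table (TSV: position, aa, [asa,] rsa)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "aa", "rsa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RSA table {path} missing columns: {sorted(missing)}")
    if df["position"].duplicated().any():
        dup = int(df.loc[df["position"].duplicated(), "position"].iloc[0])
        raise ValueError(f"duplicate position {dup} in {path}")
    if (df["rsa"] < 0).any():
        raise ValueError(f"negative RSA in {path}")
    has_asa = "asa" in df.columns
    residues = [
        (
            int(row.position),
            str(row.aa),
            float(row.asa) if has_asa else None,
            float(row.rsa),
        )
        for row in df.itertuples()
    ]
    residues.sort(key=lambda r: r[0])
    return RSAProfile(residues)


def write_rsa_table(profile: RSAProfile, path) -> None:
    """Serialise a profile as the TSV dialect read_rsa_table accepts."""
    df = pd.DataFrame(
        profile.residues, columns=["position", "aa", "asa", "rsa"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
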