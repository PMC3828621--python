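"""RSA computation and exposure classification from DSSP output.

Writes a miniature classic-format DSSP file, parses chain A, converts the
ACC (ASA) values to RSA with the Tien max-ASA scale, and prints each
residue's exposure class under the three-class scheme.
"""

import tempfile
from pathlib import Path

from designvar import THREE_CLASS, classify_exposure, compute_rsa, parse_dssp

HEADER = (
    "==== SECONDARY STRUCTURE DEFINITION BY THE PROGRAM DSSP ====\n"
    "REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O\n"
)


def dssp_line(serial: int, aa: str, acc: int) -> str:
    prefix = f"{serial:5d}{serial:5d} A {aa}"
    return prefix + " " * (34 - len(prefix)) + f"{acc:4d}"


residues = [("L", 5), ("A", 20), ("K", 150), ("G", 60)]
text = HEADER + "\n".join(
    dssp_line(i + 1, aa, acc) for i, (aa, acc) in enumerate(residues)
) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "mini.dssp"
    path.write_text(text)
    profile = compute_rsa(parse_dssp(path, chain="A"))

print(f"{'pos':>3} {'aa':>2} {'ASA':>6} {'RSA':>6}  class")
for pos, aa, asa, rsa in profile.residues:
    cls = classify_exposure(rsa, THREE_CLASS)
    print(f"{pos:>3} {aa:>2} {asa:>6.1f} {rsa:>6.3f}  {cls}")
print()
print("RSA = ASA / max-ASA(residue); buried <= 0.05 < partially buried <= 0.25 < exposed.")
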