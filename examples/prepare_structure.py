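"""Prepare a structure: assign charges/radii at pH 7.4 and report net charge.

Builds a small synthetic peptide with one acidic (Asp), one basic (Lys) and
one histidine residue, assigns model-pKa formal charges, and writes a PQR.
"""

from pathlib import Path

from esimap import (
    TitrationModel,
    ToySpec,
    assign_parameters,
    make_toy_structure,
    net_charge,
    write_pqr,
)
from esimap.structure_io import charged_residues

s = make_toy_structure(ToySpec(3, {1: -1, 2: +1}, label="DKH"),
                       residue_names={1: "ASP", 2: "LYS", 3: "HIS"})
titration = TitrationModel(pH=7.4, termini_charged=False)
s = assign_parameters(s, titration)

q_int, q_raw = net_charge(s)
charged = charged_residues(s, titration)
out = Path("scratch_example_out")
out.mkdir(exist_ok=True)
write_pqr(s, out / "dkh.pqr")

print(f"net charge: {q_int} ({q_raw:+.3f} e)")
print(f"charged residues at pH 7.4: "
      f"{[f'{name}{key[1]}' for key, name, _ in charged]}")
print("His is neutral at pH 7.4 (model pKa 6.30), so Asp(-1) and Lys(+1)")
print(f"cancel to a net charge of 0. PQR written to {out / 'dkh.pqr'}.")
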