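"""Derive a degenerate consensus primer from a conserved alignment window.

The minimal IUPAC covering code per column guarantees the primer matches
every reference in the window with zero mismatches; its degeneracy is the
product of per-position alternative counts.
"""

from ampliclade.conservation import Msa
from ampliclade.primers import (
    codhech_primer_sets, consensus_primer, degeneracy, expand, set_degeneracy,
)
from ampliclade.seqio import NucRecord

rows = [
    "GTCGTATTGATCCATTTGGC",
    "GTCGTATCGATCCATTTGGC",
    "GTCGTATTGATCCTTTTGGC",
    "GTCGTATCGATCCTTTTGGC",
]
window = Msa.from_records(NucRecord(f"seq{i}", s) for i, s in enumerate(rows))
primer = consensus_primer(window, max_degeneracy=64, name="designed_fw")
print(f"consensus primer : {primer.seq}")
print(f"degeneracy       : {degeneracy(primer)} "
      f"(= number of concrete 20-mers it represents)")
print(f"expansions       : {', '.join(expand(primer))}")

print("\nThe six published clade-targeted sets and their degeneracy products:")
for ps in codhech_primer_sets():
    print(f"  {ps.name:9s} {ps.target_clade:5s} degeneracy {set_degeneracy(ps):3d} "
          f"amplicon {ps.expected_size} bp")
print("A degeneracy of 64 means the PCR mix contains 64 distinct "
      "oligonucleotide species.")
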