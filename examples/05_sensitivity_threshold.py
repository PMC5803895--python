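"""How many reads does detection need?

Samples N error-free 150 bp reads from a 1.3 kb virus-like transcript (50%
protein identity to a database entry), assembles them with the de Bruijn
mini-assembler, and searches the contigs. The table gives the detection
rate per N over 20 replicates; the threshold is the smallest N at which at
least half the replicates succeed.
"""

from viroscreen import SequenceRecord, VpdDatabase
from viroscreen.quant import sensitivity_experiment
from viroscreen.synthdata import (
    _rand_nt,
    _rng,
    back_translate,
    make_toy_vpd,
    mutate_protein,
    template_bundle,
)

templates = template_bundle()
vpd = VpdDatabase(entries=make_toy_vpd())

prot = mutate_protein(templates["tpl_rhabdo_N"], 0.5, seed=1)
nt = back_translate(prot, _rng(1, 77))
transcript = SequenceRecord("tx", nt + "TAA" + _rand_nt(_rng(1, 78), 7))
print(f"transcript: {len(transcript.residues)} bp, "
      f"protein at 50% identity to {vpd.entries[0].protein_id}")

table, min_n = sensitivity_experiment(
    transcript, vpd.records(), n_values=[2, 4, 6, 8, 10, 12, 14],
    replicates=20, seed=1,
)
print(table.to_string(index=False))
print(f"detection threshold (rate >= 0.5): {min_n} reads")
# Contigs require two overlapping reads, so detection turns on as soon as
# read starts begin to overlap - around a handful of reads for a 1.3 kb
# transcript, comfortably below ten.
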