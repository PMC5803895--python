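"""Curate a viral protein database and place a hit phylogenetically.

Part 1: database curation - viral proteins with close cellular homologs
(here, one identical to a host protein and one carrying a superoxide-
dismutase motif) are purged, with machine-checkable reasons.

Part 2: phylogeny - a diverged family of proteins is aligned progressively,
Kimura-corrected distances are computed, and a neighbor-joining tree is
printed as Newick. Sequences diverged from the same template cluster
together, the way transposon-encoded proteins cluster away from true viral
proteins.
"""

from viroscreen import (
    Alphabet,
    SequenceRecord,
    ViralProteinEntry,
    VpdDatabase,
    neighbor_joining,
    progressive_align,
    protein_distance,
    purge_cellular_homologs,
    write_newick,
)
from viroscreen.motifs import cellular_blocklist
from viroscreen.synthdata import make_toy_vpd, mutate_protein, template_bundle

# --- Part 1: curation -------------------------------------------------
templates = template_bundle()
host_seq = templates["tpl_gag"].sequence  # stands in for a host protein
sod = next(m.consensus for m in cellular_blocklist()
           if m.name == "SUPEROXIDE_DISMUTASE")
entries = list(make_toy_vpd())
entries.append(ViralProteinEntry(
    "viral_host_twin", "Toy ascovirus", "Ascoviridae", "I", "dsDNA", True,
    host_seq,
))
entries.append(ViralProteinEntry(
    "viral_sod", "Toy ascovirus", "Ascoviridae", "I", "dsDNA", True,
    templates["tpl_ORF7"].sequence[:80] + sod
    + templates["tpl_ORF7"].sequence[80:160],
))
vpd = VpdDatabase(entries=entries)
host = [SequenceRecord("host_gag_like", host_seq, alphabet=Alphabet.PROTEIN)]
curated = purge_cellular_homologs(vpd, host)
print(f"curation: {len(vpd)} -> {len(curated)} proteins")
for pid, reason, evidence in curated.removal_log:
    print(f"  removed {pid}: {reason} ({evidence})")

# --- Part 2: phylogeny ------------------------------------------------
base = templates["tpl_rhabdo_P"]
family_a = [mutate_protein(base, 0.9, seed=s) for s in (11, 12, 13)]
family_b = [mutate_protein(base, 0.55, seed=s) for s in (21, 22)]
labels = ["A1", "A2", "A3", "B1", "B2"]
msa = progressive_align(family_a + family_b)
dm = protein_distance(msa, labels=labels, model="KIMURA")
tree = neighbor_joining(dm)
print("\nNewick:", write_newick(tree))
within_a = dm.d[0, 1]
between = dm.d[0, 3]
print(f"within-family distance A1-A2: {within_a:.3f}; "
      f"between families A1-B1: {between:.3f}")
# Distances within the tight family are far below the between-family
# distances, so the tree separates the two clusters cleanly.
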