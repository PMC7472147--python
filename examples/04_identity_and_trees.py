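"""Pairwise identity, species demarcation and a neighbor-joining tree.

Aligns a query NS1 protein against reference replication proteins
(BLOSUM62, gap open 11 / extend 1), applies the ICTV-style rule that a new
parvovirus species must be < 85% identical to every known NS1, and builds an
NJ tree from the pairwise distance matrix.
"""

import numpy as np

from viroseek import annotate as ann
from viroseek import synthetic_data as sd
from viroseek.compare import identity_matrix, nj_tree, write_newick

community = sd.default_demo_community(seed=1, n_pairs=1000,
                                      host_length=20_000, bacterial_length=10_000)
parvo = next(m.genome for m in community.members
             if m.genome.label.startswith("parvovirus"))
ns1 = next(o for o in parvo.truth.orfs if o.name == "NS1")

db = sd.make_protein_db(community, seed=102)
refs = {r.id: r.residues for r in db
        if r.label == "virus" and r.taxon.startswith("parvovirus")}

decision = ann.species_demarcation(ns1.peptide, refs)
print(f"closest reference: {decision.closest_reference}")
print(f"max NS1 identity: {decision.max_identity:.1f}% "
      f"-> new species candidate: {decision.is_new_species_candidate}")

seqs = {"query_NS1": ns1.peptide, **refs}
ident, dm = identity_matrix(seqs, mode="local")
print("\nlocal percent-identity matrix:")
print(ident.round(1).to_string())

tree = nj_tree(dm)
print("\nneighbor-joining tree (distances d = 1 - identity/100):")
print(write_newick(tree))
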