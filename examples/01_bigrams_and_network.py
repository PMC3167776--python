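"""Extract domain bigrams from an assignment table and build the network.

A bigram is an adjacent pair of distinct domains in one protein with a
gap below 30 residues; collapsing bigrams over all proteins gives an
undirected network over domain types.
"""

import io

from bigramnet import build_network, parse_assignments, peripheral_domains
from bigramnet.assignments import all_bigrams, extract_bigrams

TABLE = """\
#genome_id\tprotein_id\tdomain_id\tregion
hs\tp1\tSH3\t1-60
hs\tp1\tSH2\t70-160
hs\tp1\tKinase\t180-430
hs\tp2\tSH2\t5-95
hs\tp2\tKinase\t140-390
hs\tp3\tPH\t1-110
hs\tp3\tKinase\t130-420
hs\tp4\tActin\t1-370
"""

by_genome = parse_assignments(io.StringIO(TABLE))
archs = by_genome["hs"]

for arch in archs:
    pairs = [(b.upstream, b.downstream, b.gap) for b in extract_bigrams(arch)]
    print(f"{arch.protein_id}: domains={arch.domain_ids} bigrams={pairs}")

periph = peripheral_domains(archs)
net = build_network(all_bigrams(archs), include_isolated=periph)
print(f"\nnetwork: {net.n_vertices} domains, {net.n_edges} bigram edges")
print("edge counts:", {tuple(sorted(e)): net.edge_count(*e) for e in net.graph.edges})
print("peripheral (never in a bigram):", sorted(periph))
# p2's SH2-Kinase gap is 44 residues (>= 30), so only p1 links them;
# Actin occurs alone, making it a network peripheral domain.
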