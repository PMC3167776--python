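"""The peripheral-hub toy: degree is not networking versatility.

Hub F has the joint-highest degree (4) and touches the core directly,
yet its shell index is only 1: once the leaves peel at k = 2, F has a
single remaining edge and peels too.  The shell (networking
versatility) index measures how deep a domain sits in the network's
nested cores, not how many partners it has.
"""

from bigramnet import decompose, from_edges, innermost_core, k_core

net = from_edges(
    [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
     ("A", "F"), ("F", "L1"), ("F", "L2"), ("F", "L3")]
)
table = decompose(net)

print("domain  degree  shell")
for dom in sorted(table.shells):
    print(f"{dom:6}  {net.degree(dom):6}  {table.shells[dom]:5}")

print("\n2-core members:", sorted(k_core(net, 2).vertices))
print("innermost core :", sorted(innermost_core(table)),
      f"(max shell {table.max_shell}, {table.nested_core_count} nested cores)")
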