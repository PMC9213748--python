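"""Gene-order extraction, order maps and breakpoint distances."""

from mitocompare.gene_order import (
    CANONICAL_ORDER,
    GeneOrder,
    breakpoint_distance,
    extract_gene_order,
    order_map,
)
from mitocompare.simulate import SimConfig, generate_ancestor

genome, _ = generate_ancestor(SimConfig(seed=11))
order = extract_gene_order(genome)
print("extracted order:", " ".join(order.labels()))

result = breakpoint_distance(order, CANONICAL_ORDER)
print(f"vs canonical actiniarian order: {result.breakpoints} breakpoints "
      f"(identical={result.identical}) over {result.shared_genes} shared genes")

# a transposition of cox1 and cox3 creates breakpoints at the moved edges
labels = [g for g, _ in order.genes]
i, j = labels.index("cox3"), labels.index("cox1")
labels[i], labels[j] = labels[j], labels[i]
swapped = GeneOrder("swapped", tuple((g, 1) for g in labels))
print(f"after swapping cox1/cox3: "
      f"{breakpoint_distance(order, swapped).breakpoints} breakpoints")

print(order_map([order, swapped], anchor="ND5").to_string(index=False))
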