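# bmgraph

Colored best match graphs for orthology inference: compute them from gene
trees, recognize them among arbitrary vertex-colored digraphs, and
reconstruct the unique least resolved tree that explains them.

## The problem

Reciprocal-best-hit methods start orthology detection by recording, for
each gene `x` of species `A`, the genes of every other species `B` that
are evolutionarily closest to `x`.  Relative to the (unknown) gene tree
`T` with species coloring `σ`, gene `y` is a **best match** of `x` when

    σ(y) ≠ σ(x)   and   lca(x, y) ⪯ lca(x, y′)  for all y′ with σ(y′) = σ(y).

The digraph of all best-match arcs, vertices colored by species, is the
**colored best match graph** (cBMG) `G(T, σ)`.  Empirical best-hit graphs
should ideally be of this form, which raises two questions this package
answers exactly:

* **Recognition** — is a given vertex-colored digraph `(G, σ)` a cBMG?
* **Reconstruction** — if so, what is the unique **least resolved tree**
  (LRT), the tree explaining `G` from which no inner edge can be
  contracted without changing the graph?

Recognition runs per weak component and reduces to two colors: `(G, σ)`
is a cBMG iff every two-color induced subgraph is a 2-cBMG and the union
of their triples is consistent.  For two colors the package implements
three mutually checking routes: the neighborhood axioms (N1)–(N3) on
thinness classes with the hierarchy of extended reachable sets
`R'(α) = R(α) ∪ Q(α)`, informative triples with the Aho/BUILD supertree
algorithm, and redundant-edge contraction.  All three produce the same
canonical LRT; negative answers carry a machine-readable certificate.
Exhaustive brute-force oracles (all rooted phylogenetic trees on ≤ 6
leaves) certify every negative example.

## Worked example

One duplication predating the split of two grasses, plus an outgroup.
Trees are Newick with a leaf→species TSV (or inline `label|species`):

```
$ cat ex.nwk
(((a1,b1),(a2,b2)),c1);
$ cat ex.tsv
a1	amborella
b1	oryza
a2	amborella
b2	oryza
c1	zea
$ bmg compute --tree ex.nwk --colors ex.tsv --out ex
5 vertices, 12 arcs
```

`ex.arcs.tsv` now holds the best-match arcs: `a1↔b1` and `a2↔b2` (each
paralog pairs with its own co-ortholog), everything points at the single
zea gene `c1`, and `c1` points back at all four.  Recognizing the graph
recovers the tree — except that the root edge is redundant (contracting
it changes no best match), so the LRT is less resolved than the input:

```
$ bmg recognize --graph ex.vertices.tsv,ex.arcs.tsv
((a1|amborella,b1|oryza),(a2|amborella,b2|oryza),c1|zea);
$ bmg triples --graph ex.vertices.tsv,ex.arcs.tsv
a1,b1|a2
a1,b1|b2
a2,b2|a1
a2,b2|b1
```

The four informative triples pin both cherries; no triple separates the
cherries from `c1`, which is exactly why the LRT keeps the root polytomy.
On a non-cBMG, `bmg recognize` exits 1 and prints a JSON certificate
(failed axiom, missing out-arc, inconsistent triples, or final mismatch);
`bmg oracle` cross-checks any graph with ≤ 6 vertices by exhaustion, and
`bmg fixtures --name consistent-non-bmg` emits the classic 4-vertex graph
whose informative triples are consistent even though no tree explains it.

The same operations are available as a library:

```python
from bmgraph import parse_newick, bmg_from_tree, recognize_ncbmg

tree = parse_newick("((x|human,y|mouse),z|mouse);")
G = bmg_from_tree(tree)                 # arcs: x↔y, z→x
result = recognize_ncbmg(G)
print(result.lrt.newick())              # ((x|human,y|mouse),z|mouse);
```

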