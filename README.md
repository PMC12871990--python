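# cellph

Topological shape signatures for single cells.  `cellph` compares cells in
a microscopy population by the **persistent homology of their boundary
contour**: each cell is summarised by the dimension-0 persistence diagram of
the radial distance function measured from the centre of mass of its
nucleus, and two cells are compared with the 2-Wasserstein distance between
their diagrams.  On top of this the package provides the surrounding
analysis a cell biologist needs — hierarchical clustering with a tree-purity
score, classical MDS embeddings, ROC evaluation against known groups, a
sensitivity experiment for the nucleus position — plus three classical
baseline contour distances (aspect ratio, elliptic Fourier descriptors, and
an elastic SRVF distance) for comparison.

## The signature

A cell contour is an ordered simple closed polyline; together with an
interior base point *C* (the nucleus centre of mass) it defines a cyclic
degree-2 graph *G* with the vertex filtration

&nbsp;&nbsp;&nbsp;&nbsp;*f*(*v*) = ‖*v* − *C*‖,&nbsp;&nbsp;&nbsp;&nbsp;*f*(*e* = (*u*, *v*)) = max(*f*(*u*), *f*(*v*)).

Sweeping the sub-level sets *G*<sub>a</sub> = *f*<sup>−1</sup>((−∞, a]) and
tracking connected components under the elder rule yields a dimension-0
persistence diagram — one point per radial "inlet" of the cell, born at a
local minimum of the radial distance and dying where its arc merges with an
older one.  The single essential component is paired with the birth of the
essential 1-cycle (the value at which the last vertex enters, max *f*), so
the diagram is a finite multiset of (birth, death) points that records both
the lobedness and the physical size of the cell.  Diagrams are compared
with the p-Wasserstein distance

&nbsp;&nbsp;&nbsp;&nbsp;W<sub>p</sub>(D₁, D₂) = (min<sub>matching</sub> Σ ‖X − f(X)‖<sup>p</sup>)<sup>1/p</sup>,

where unmatched points may pay their orthogonal projection onto the
diagonal ("ghost" points), making W<sub>p</sub> a true metric; p = 2 is the
default.  Before filtering, pixel-trace contours are *cleaned*: maximal
runs of consecutive vertices sharing an x or y coordinate are collapsed to
their endpoints, which shrinks staircase boundaries without materially
moving the diagram (persistence is stable under bounded value changes).

## Worked example

Two synthetic populations — large star-shaped cells with 4–6 lobes and
small smooth ellipses — are generated, turned into diagrams, clustered and
scored:

```python
import cellph as cp

# the small illustrative filtration (14 cyclic vertex values)
g, f = cp.worked_example_graph()
print(cp.sublevel_diagram0(g, f).points.tolist())
# [[1.0, 5.0], [3.0, 4.0], [3.0, 5.0], [3.0, 5.0], [4.0, 5.0], [4.0, 5.0], [4.0, 5.0]]

specA, specB = cp.synthetic.example_populations(n_per_group=10, seed=0)
contours, centres, labels = cp.two_population(specA, specB)
diagrams = [cp.diagram_for_cell(contours[c], centres[c]) for c in sorted(contours)]
m = cp.all_pairs(diagrams, p=2)

tree = cp.hca(m, "average")
groups = cp.cut(tree, 2).groups()
print({k: len(v) for k, v in groups.items()})      # {'A': 10, 'B': 10}
for lk in cp.LINKAGES:
    t = cp.hca(m, lk)
    print(lk, [round(cp.purity(set(mem), t), 3) for mem in groups.values()])
# average  [1.0, 1.0]
# single   [1.0, 1.0]
# complete [1.0, 1.0]
# ward     [1.0, 1.0]

res = cp.roc(m, labels)
print(round(res.auc, 3), round(res.pauc10, 4))     # 0.992 0.0956
```

The diagram of the illustrative filtration has one essential point (1, 5)
plus finite points with multiplicities — (3, 5) twice, (4, 5) three times —
one per radial inlet.  The two synthetic populations are recovered exactly
by the average-linkage cut (the two 10-cell clusters), every linkage agrees
with that partition (purity 1.0 throughout), and the pairwise ROC confirms
near-perfect separation (AUC 0.992; pAUC10 close to its 0.1 maximum).

## Command line

`cellph` exposes the same pipeline as subcommands:

```sh
cellph synth --spec spec.json --out cells/          # synthetic populations
cellph diagram cells/stars-000.csv --center 0,0     # one persistence diagram
cellph distmat --input cells/ --metric ph --out d.csv
cellph cluster --distmat d.csv --linkage average --k 4 --out out/
cellph purity  --distmat d.csv --k 4 --out purity.csv
cellph mds     --distmat d.csv --out mds.csv
cellph roc     --distmat d.csv --labels cells/labels.csv --out roc
cellph sensitivity --input cells/ --labels cells/labels.csv --out sens.csv
cellph run --input cells/ --labels cells/labels.csv --out results/
```

`--metric` selects `ph`, `aspect`, `fourier` or `elastic`;
`--microns-per-pixel` rescales pixel contours (d = n × s).

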