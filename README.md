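# disnet

A toolkit for building and interrogating molecular disease networks. It
covers four workflows that recur in systems-level studies of
neurodegenerative disease (and of disease genetics generally):

1. **PPI queries** — induce the subnetwork on a gene list, expand the
   k-hop neighborhood of a seed protein (degree capped at 3 by default),
   and filter/group the result by function, phenotype or pathway
   annotation. Output is Cytoscape SIF with a node-attribute sidecar.
2. **Projections** — collapse a disease–gene association table onto a
   weighted disease–disease network (edge weight = shared genes, or
   PPI-interacting gene pairs), and rank pathway crosstalk by shared
   molecular components.
3. **SBML export** — turn a signal–gene–protein pathway (six typed,
   signed interaction classes: Sig-Sig, Sig-Prot, Sig-Gene, Prot-Prot,
   Prot-Gene, Gene-Gene) into an SBML Level 2 Version 4 model with
   first-order mass-action rate laws, ready for a CellDesigner-class
   simulator once real kinetics are supplied.
4. **Boolean analysis** — parse regulatory rules written in the
   `$node[i] = expr;` syntax (`!`, `&`, `|`, parentheses; precedence
   NOT > AND > OR), run synchronous dynamics, exhaustively enumerate all
   2^N states, and report singleton (fixed-point) and cyclic attractors
   with basin sizes. A signed-threshold semantics is also provided:
   node *i* switches on iff Σ_j a_ij·S_j(t) ≥ 1 with a_ij = +1 for
   activation and −1 for inhibition. Mutants are modeled by clamping
   nodes to 0 (knockout) or 1 (overexpression).

The model at the core of the Boolean engine is the synchronous Boolean
network G = (V, E): each node holds a binary state S_i(t) ∈ {0, 1}, and all
nodes update simultaneously, S(t+1) = F(S(t)). Because the state space is
finite and F deterministic, every orbit ends in a cycle of F; those cycles
are the attractors, and the set of states whose orbits reach a given
attractor is its basin. Basins partition the 2^N states.

## Worked example: the mammalian cell-cycle network

The package bundles a 10-node Boolean model of the mammalian cell cycle
(CycD, Rb, E2F, CycE, CycA, p27, CDC20, CDH1, UbcH10, CycB) whose rules
contain 49 regulator literals. Attractor states are printed as binary
strings with node 1 leftmost.

```
$ disnet boolean attractors
N=10    edges=49        states=1024
singleton attractors: 1
  0100010100    basin=512
cyclic attractors: 1
  period=7      basin=512       1000001110 -> 1010000110 -> 1011000100 -> 1011100100 -> 1001100000 -> 1000100011 -> 1000101011
```

The single fixed point `0100010100` (Rb, p27 and CDH1 on, all cyclins off)
is the quiescent G0 state; half of the 1024 states (all those with CycD
off) flow into it. The other half — growth-factor present, CycD on — fall
onto a seven-state cycle that walks the network through the G1/S/G2/M
phase sequence. Knocking out the tumor suppressor Rb removes the resting
state entirely:

```
$ disnet boolean mutant --clamp 2=0
singleton attractors: 0
cyclic attractors: 2
```

With Rb clamped off the network can only cycle — the restriction point is
lost.

The PPI side has an equally small bundled fixture:

```
$ disnet ppinet --genes A2M,APP,APOE --out net.sif
3 nodes 2 edges net.sif
A2M     <->     APOE
APOE    <->     APP

$ disnet neighborhood --seed ANG --degree 1 --out ang.sif
degree  nodes_cumulative        nodes_new       edges_cumulative
1       8       7       7
```

Angiogenin (ANG) has exactly seven first-neighbor proteins in the fixture,
grouped by the annotation table into regulation of angiogenesis, cardiac
muscle development, vasculature development and apoptosis.

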