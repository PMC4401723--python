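# qapmatch

Fast approximate graph matching by Frank–Wolfe on the **indefinite**
relaxation of the quadratic assignment problem (QAP).

## The problem

Given two graphs with adjacency (or flow/distance) matrices
*A*, *B* ∈ ℝⁿˣⁿ, the graph matching problem asks for the vertex alignment
minimizing edge disagreements,

    min_{P ∈ 𝒫} ‖AP − PB‖²_F ,

over permutation matrices 𝒫.  Since
‖AP − PB‖²_F = tr(AᵀA) + tr(BBᵀ) − 2 tr(APBᵀPᵀ), this is equivalent to the
Koopmans–Beckmann QAP, min tr(APBᵀPᵀ) (or its maximization for matching
overlap), an NP-hard problem.  The motivating application is connectomics:
aligning brain graphs — e.g. the *C. elegans* chemical connectome, a directed
graph on 279 neurons weighted by synapse counts — where graph-structural
comparison requires a vertex correspondence.

## The algorithm

The solver relaxes 𝒫 to its convex hull 𝒟, the doubly stochastic matrices
(Birkhoff polytope), and keeps the **indefinite** quadratic objective rather
than the convex one.  Frank–Wolfe (conditional gradient) iterations then run
entirely with O(n³) primitives:

1. gradient of f(P) = −tr(APBᵀPᵀ):  ∇f(P) = −APBᵀ − AᵀPB;
2. direction: Q = argmin_{𝒟} tr(∇f(P)ᵀQ) — a linear assignment problem,
   solved exactly (Hungarian/Jonker–Volgenant);
3. step: exact line search of the quadratic g(α) along P → Q;
4. update P ← P + α(Q − P);
5. after convergence, project onto 𝒫 via one more LAP,
   max_P tr(P_final Pᵀ).

For asymmetric graphs the indefinite relaxation of the self-match problem has
the identity as its **unique** minimizer over 𝒟, so matching shuffled
isomorphic graphs is provably well-posed; the convex relaxation
‖AD − DB‖²_F does not have this property (on regular graphs it bottoms out at
the uninformative barycenter J = 𝟙𝟙ᵀ/n).  Because the relaxed landscape is
multimodal, the solver supports multi-restarts: restart 0 from J, the rest
from Sinkhorn-randomized points (J + K)/2.

## Worked example

Match a shuffled synthetic connectome (279 vertices, directed,
synapse-count weights) back to itself:

```python
from qapmatch import FAQMatcher
from qapmatch.synthetic import connectome_like, shuffle_graph, match_accuracy

A = connectome_like(n=279, density=0.03, weight_mean=3.0, seed=0)
pair = shuffle_graph(A, seed=1)          # B = Q A Q^T, Q uniformly random
m = FAQMatcher(maximize=True).fit(pair.A, pair.B)
print("objective :", m.score_)           # objective : 33255.0
print("accuracy  :", match_accuracy(m.perm_, pair))   # accuracy  : 1.0
```

The printed objective 33255.0 equals tr(AAᵀ) = Σ a²uv, the provable maximum
of the overlap — the matcher found the exact unshuffling (accuracy 1.0) from
a single barycenter start, in 2 Frank–Wolfe iterations.

The same machinery is exposed as plain functions (`faq`, `qcv_solve`,
`frank_wolfe`, `solve_lap`, …) and as a CLI:

```
qapmatch match --a a.csv --b b.csv --obj max --restarts 3 --seed 0 --out r.json
qapmatch qaplib tests_data/*.dat --restarts 100 --seed 0 --csv table.csv
qapmatch simulate --n 50 --reps 100 --seed 0
qapmatch scaling --sizes 50,100,200 --reps 3
```

`qapmatch qaplib` reads standard QAPLIB `.dat` instance files (and `.sln`
solution files for gap reporting); supply your own copies of the benchmark
library — nothing is downloaded.

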