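# Methods

## Model and conventions

The package optimizes the Koopmans–Beckmann trace objective
f(P) = tr(APBᵀPᵀ) over permutation matrices, either minimizing (assignment
cost) or maximizing (graph-matching overlap; internally the sign is flipped
and everything minimizes).  One permutation-matrix convention is used
everywhere: `P[u, pi(u)] = 1`, so tr(APBᵀPᵀ) = Σ_{u,v} a_uv · b_{π(u)π(v)}.
Permutations are 0-based internally; 1-based indices appear only in QAPLIB
`.sln` files and human-facing printouts.  In QAPLIB `.dat` files the first
matrix is read as A, the second as B.  (A few historical QAPLIB families
swap the roles; for symmetric instances the objective is unaffected, and the
reader deliberately does not special-case families — users matching
asymmetric `.dat` files against published optima should check orientation.)

## The solver

Frank–Wolfe on the indefinite relaxation over the doubly stochastic
matrices:

* **Gradient** ∇f(P) = ±(APBᵀ + AᵀPB).
* **Direction**: the linearized subproblem over the Birkhoff polytope always
  has a vertex solution, so it is solved exactly as a linear assignment
  problem with `scipy.optimize.linear_sum_assignment` (O(n³)).  LAP
  tie-breaking is whatever that solver produces, held fixed; tests assert
  optimal values, never a particular tied permutation.
* **Step size**: the objective restricted to the segment P → Q is an exact
  quadratic c₀ + c₁α + c₂α²; the minimizer over [0, 1] is the interior
  critical point when c₂ > 0 and it lies in (0, 1), else the better
  endpoint.  Exact ties return the larger α (progress toward the LAP
  vertex); an exactly zero direction (Q = P) returns α = 0.  The update is
  the convex combination P + α(Q − P), which keeps every iterate feasible to
  round-off; iterates are never renormalized.
* **Stopping**: α = 0, or ‖P⁽ⁱ⁾ − P⁽ⁱ⁻¹⁾‖_F < tol (default 1e−6), or
  max_iter (default 100) iterations.  A gradient-norm criterion exists but
  is off by default — stalls are already caught by the step rules.
* **Projection**: the final doubly stochastic iterate is projected to the
  nearest permutation by maximizing tr(P_final Pᵀ), one more LAP.  The
  reported objective is recomputed exactly at that permutation, never
  carried over from the relaxation.
* **Restarts**: restart 0 starts at the barycenter J = 𝟙𝟙ᵀ/n (so a
  single-restart run is fully deterministic); restarts r ≥ 1 start at
  (J + K)/2 where K is an i.i.d. uniform matrix pushed through 10 Sinkhorn
  balancing passes, sub-seeded with seed + r so a k-restart run is nested in
  a (k+1)-restart run (restart dominance holds exactly).  Ten Sinkhorn
  passes leave row/column sums ~1e−7 off at small n, so the averaged start
  is balanced further — at initialization only — until its residual is
  ≤ 1e−10, comfortably inside the 1e−8 feasibility tolerance enforced on all
  doubly stochastic matrices.

`qcv_solve` / `ConvexMatcher` run the identical loop on the convex
relaxation ‖AD − DB‖²_F (value, gradient 2Aᵀ(AD−DB) − 2(AD−DB)Bᵀ, and its
own exact segment quadratic).  It exists as a comparator: on any graph with
constant row and column sums, AJ = JA makes the convex objective 0 at the
barycenter, so its relaxed solution carries no alignment information, while
the indefinite relaxation of an asymmetric self-match has the identity as
unique minimizer.

`scipy.optimize.quadratic_assignment(method="faq")` implements the same
iteration; it is used in the test suite as an independent cross-check (the
two agree bit-for-bit on deterministic barycenter runs in the minimize
sense) and nowhere in the implementation.

## Synthetic data

* `er_graph(n, p)` — simple Erdős–Rényi graphs, hollow 0/1 adjacency,
  undirected or directed; p defaults to log(n)/n, the sparse/connectivity-
  threshold regime used throughout the experiments.
* `connectome_like(n=279, density=0.03, weight_mean=3)` — a stand-in for a
  chemical connectome: directed Bernoulli skeleton with i.i.d. geometric
  weights on {1, 2, …}.  The density gives ≈ 2300 directed connections on
  279 vertices and the geometric law is a single-parameter, integer-valued,
  heavy-enough-tailed model for synapse counts; real connectomes have
  degree heterogeneity, reciprocity and community structure this generator
  does not emulate, so perfect recovery here shows the solver exploits
  generic weighted-digraph asymmetry, not biological structure.  Real
  connectome matrices can be supplied through `read_matrix`.
* `shuffle_graph` — B = QAQᵀ with Q uniform (Fisher–Yates); accuracy is the
  fraction of vertices correctly unshuffled, checked against the stored
  truth (a unit test pins the shuffle/unshuffle direction to prevent
  transposition bugs).
* `known_optimum_instance(n)` — a minimization QAP whose global optimum is
  provable: A a directed ER adjacency, B = 2·𝟙𝟙ᵀ − A.  On the Birkhoff
  polytope tr(ADBᵀDᵀ) = 2ΣA − tr(ADAᵀDᵀ), and by Cauchy–Schwarz on 0/1
  entries tr(APAᵀPᵀ) ≤ tr(AAᵀ) with equality at the identity, so the
  minimum is exactly ΣA (the edge count).  These instances exercise the
  deterministic single-start path end-to-end (including QAPLIB file I/O)
  with a certificate of optimality and no external benchmark files.
* `weighted_regular_graph(n, k)` — sum of k weighted random permutation
  matrices: constant row/column sums (the convex relaxation degenerates at
  J) yet generically asymmetric, the construction used for the
  indefinite-vs-convex contrast.

## Choice of graph orientation

The shuffled-self-match experiments default to **directed** ER graphs.
Empirically, single barycenter-start matching recovers directed ER shuffles
at p = log(n)/n in every trial across n = 30–100, while undirected graphs at
the same density are recovered only ~30–55% of the time (degrading with n) —
a behavior confirmed identically by the independent scipy implementation,
i.e. a property of the method at those conditions, not of this code.  An
undirected adjacency carries half the independent entries, and its symmetric
landscape retains more spurious local optima.  `directed=False` selects the
undirected regime for study.

## Problem sizes

Test-suite and acceptance-script sizes were chosen so each claim is
demonstrated at the smallest scale where it is reliably observed: exhaustive
oracles up to n = 9 (9! permutation sweeps), deterministic known-optimum
instances at n = 20–50, shuffle recovery at n = 50 (20 trials) and n = 279
(connectome-like), the restart study at n = 8–9 with 100 restarts, and the
regular-graph contrast at n = 16 with 50 restarts (enough that the
indefinite relaxation's global optimum is found in every trial while the
convex comparator never recovers exactly).

## Known limitations

* No seeded/partial matchings, no padding for unequal vertex counts, no
  multi-graph matching, and no vertex-similarity linear term.
* The solver finds local optima of an indefinite program: single-start
  results on hard benchmark families (e.g. uniform-random QAPs) are several
  percent above the global optimum, and restarts close that gap only
  stochastically — a 100-restart run can still miss the optimum of an
  arbitrary random instance.
* Dense O(n²) memory and O(n³) per-iteration time: practical to a few
  thousand vertices.
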