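# Methods

## The boolean program calculus and the exhaustive test

Wall-following controllers are finite trees over twelve boolean
variables — eight space-fixed wall-contact sensors (`n`, `ne`, `e`,
`se`, `s`, `sw`, `w`, `nw`) and four move indicators (`north`, `east`,
`south`, `west`) — built from `If[c,t,f]`, `&&`, `||`, `!`, `True` and
`False`.  The dialect is Mathematica-flavoured: `!` binds tighter than
`&&`, which binds tighter than `||`; `If` brackets are literal.  The
calculus is pure, so the evaluator is defined by full recursion;
short-circuiting would be unobservable.

The semantic fingerprint of a program is its **truth vector**: its
output on all 2¹² = 4,096 assignments.  Assignment *i* binds the
variables, in the order `(n, ne, e, se, s, sw, w, nw, north, east,
south, west)`, to the 12-bit binary expansion of *i* with `n` as the
most significant bit.  Disagreement counts are invariant to this
order; fixing it merely makes exported truth vectors exchangeable
between implementations.  Truth vectors are computed by structural
recursion with one vectorized numpy operation per tree node over all
4,096 assignments; the test suite checks this path element-wise
against an independently coded per-assignment interpreter.

**Transcriptions.**  The three champion listings are stored verbatim
except for three documented interventions: (i) italic markers `*s*`
etc. are typesetting and are skipped by the lexer; (ii) Sol2 and Sol3
are printed twice each — one copy is stored; (iii) Sol1's listing ends
with a dangling `, ||south` *after* its bracket-balanced expression has
closed.  We treat the tail as typesetting debris and ship the bare
bracket-balanced expression.  This is a judgment call, made on the only
available evidence: with the tail dropped, Sol1's disagreement counts
with Sol2 and Sol3 are 2,328 and 2,312 — both consistent with the
reported "more than 2,000" — whereas attaching `||south` as a top-level
disjunct yields 2,000 and 1,568, contradicting that bound.  The
verbatim printed fragment is packaged alongside
(`sol1_printed.txt`) so the judgment can be audited.  Sol1's exact
semantics cannot be certified from the printed text; the Sol2–Sol3
count of 1,216 involves only the cleanly printed programs.

## The grid world

Coordinates are (row, column), 0-based, north = row − 1, east =
column + 1 — some convention must be fixed for the sensors and moves to
cohere.  Sensors report wall-occupancy of the eight neighbour cells,
space-fixed (the robot has no heading).  Moves are one cell
north/east/south/west; a blocked or off-grid move leaves the position
unchanged while the step counter still advances (the simplest
consistent physics).  "Visiting a part of the wall" is operationalized
as standing 8-adjacent to that wall cell, since the robot can never
occupy wall cells; the coverage fitness of a journey is the number of
distinct wall cells so credited, which is monotone in the journey
prefix and bounded by the world's wall count.

Closed worlds are fully wall-bordered; in open worlds the boundary is
(partly) free and everything beyond the stored grid is free but
unvisitable, so packaged open maps include a generous free apron —
this is exactly the "outside the labyrinth" regime in which champions'
behaviour becomes unpredictable.

**Controller semantics.**  The original account never states how the
four move variables enter program evaluation during control.  We adopt
a candidate-move interrogation: for each direction *d* in the fixed
priority order (north, east, south, west), evaluate the program on the
assignment {8 sensor bits} ∪ {one-hot *d*}; the first direction
answering `True` is taken, and if none does the robot stays.  This
reconciles a boolean-valued program over 12 variables with "the
program determines the next move".  An alternative reading (the move
variables encode the previous move) cannot be excluded; the choice
does not affect the exhaustive-equivalence results, which compare raw
boolean functions.  Since a program's answer depends only on the 8
sensor bits and the interrogated direction, its whole policy is
compiled to a 256-entry move table, evaluated on the 1,024 reachable
assignments; journeys then advance by table lookup, which is what makes
population-scale fitness evaluation and the all-starts perfection check
cheap.

**Perfection.**  A controller is perfect if from *every* free start it
credits every wall cell within a journey budget of 4× the wall count —
enough for first wall contact plus a full perimeter lap on any of the
packaged worlds, with slack.  The package includes a hand-written
memoryless clockwise wall-follower (orthogonal-contact rules for
straight runs and concave corners, diagonal-contact rules wrapping
convex corners, northward drift before first contact) which is verified
perfect on the closed fixture and serves as an oracle; it can also be
synthesized into an exactly equivalent boolean program by
direction-wise DNF over the 256 sensor patterns.

## Genetic programming of wall-followers

Random programs are grown depth-first: above the depth bound, internal
primitives are drawn with the bias weights IF:AND:OR:NOT = 4:4:4:2
against a terminal weight of 6, and leaves uniformly from the 12
variables plus the constants (biased selection of syntactic elements
keeps early populations from collapsing to leaves).  Fitness is mean
wall coverage over journeys of 150 steps from 8 random free starts,
frozen for the whole run (variance reduction; every member faces the
same evaluation).  Parents are chosen by a wheel of fortune
(probability ∝ fitness, uniform fallback when all fitnesses are zero),
recombined by uniform subtree exchange with probability 0.9, and
mutated with probability 0.4 by regrowing a uniformly chosen subtree.
The best member is copied unchanged each generation (elitism — makes
the best-fitness history monotone and testable); offspring exceeding
500 nodes are replaced by their parent (bloat control).  A run
terminates at the first program whose evaluation coverage is full and
which then passes the all-starts perfection check, or at the
generation cap.

Population 200 and cap 500 follow the scale used in the acceptance
experiment; the original run sizes are unstated, so all operator
parameters above are this package's choices.  With these defaults, on
the packaged 12×12 closed labyrinth, most seeds (7 of the first 10)
find a verified-perfect program within the cap, and the perfect
champions of different seeds disagree pairwise on hundreds-to-thousands
of the 4,096 states — the central dissociation: identical in-labyrinth
behaviour, distinct boolean functions.

## Neuroevolution of minimal gate networks

Networks are 2 → H → 1 (H = 30 by default), with biases realized as
"hanging input" connections on zero-threshold neurons; the activation
is a logistic sigmoid with a steepness parameter (default 1 — steeper
activations saturate gradient descent on this tiny task) and
predictions binarize at 0.5.  Each generation every member is trained
by batch gradient descent on the MSE over the gate's 4 patterns
(150 epochs at rate 2.0 by default — enough for plain training to
solve XOR from ≥ 8 of 10 random initializations at 2,000 epochs, and
for the evolutionary loop, which retrains every generation, to reach
exactness reliably).  Pruned (exactly-zero) weights are masked out of
the update: the architecture is fixed within a learning period.

Fitness is F = Q − λσ with Q = 1 − MSE (continuous, so the wheel of
fortune stays informative; exactness is checked separately via
binarization) and σ = nonzero connections / (4H + 1).  Selection uses
F − min(F) + ε since F can be negative for λ > 0.  Crossover flattens
the weights in a fixed order — per hidden unit its two input weights,
then hidden biases, then hidden→output weights, then the output bias —
cuts at a single uniform point and recombines tails.  Mutation
perturbs each surviving weight with probability 0.3 by N(0, 0.3²);
afterwards weights with |w| < 0.05 are set to exactly zero.  A weight-
decay term applying the size cost directly to learning is available
but off by default.  The champion is the highest-F network seen in any
generation that exactly implements the gate, re-verified post hoc.

With the defaults (population 20, 25 generations), champions at λ = 0
and λ = 0.1 implement both gates exactly in 10/10 seeds; the median σ
drops from ≈ 0.84 at λ = 0 to ≈ 0.6 at λ = 0.1.  The originally
rendered minimal topologies are not recoverable from text, so
minimality is asserted relationally — σ decreases with λ, and XOR
champions always retain ≥ 2 active hidden units (with no input→output
skip connections a single hidden unit can only realize h, ¬h or a
constant, and XOR is not linearly separable).

## What the synthetic fixtures do and do not show

The packaged labyrinths are representative, not replicas: the closed
map is a 12×12 wall ring with an internal protrusion, the open map a
wall figure with a free apron; the original geometries are not
recoverable.  Random worlds are Bernoulli wall fields whose free
region is made 4-connected by filling minority components, with a
fixed seed wall cell.  Passing tests therefore demonstrate the
*method* — evolvability of perfect controllers, parsimony pressure,
semantic non-equivalence — on worlds of the same character, not
pixel-level reproduction of the original figures.  Likewise the
reported 1,216 / >2,000 counts are properties of the printed programs
themselves and are reproduced exactly, whereas all statements about
freshly evolved champions are statistical, over explicit seed sets.

## Numerical and degenerate-input choices

* Truth vectors are bool arrays; disagreement is an exact integer count
  (a metric on truth vectors).
* Blocked moves are no-ops; `journey_length = 0` yields a single-state
  trajectory; a generations cap of 0 returns the best of the initial
  random population.
* Training raises on non-finite loss rather than continuing silently.
* All stochastic components consume a single `numpy` Generator;
  identical config + seed reproduces champions, histories and matrices
  bit-for-bit.

## Known limitations

* Sol1's semantics rest on a documented reconstruction; only the
  coarse >2,000 bounds, not an exact count, should be quoted for it.
* The candidate-move controller semantics is a reconstruction (see
  above); behavioural claims about the printed champions inside *our*
  labyrinth (e.g. that they are not perfect on it) depend on it and on
  the fixture geometry, and are not claims about the original setup.
* Fitness-proportionate selection with weak fitness differentials
  stalls on the GP task for some seeds; the documented guarantee is
  majority success over a seed set, not universal success, matching
  the stochastic nature of the method.
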