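# evoequiv

Evolutionary search finds *working* solutions, not *unique* ones.  This
package implements two classic experiments that make the point
quantitatively, together with the exhaustive semantic test that exposes
it:

1. **Size-penalized neuroevolution of logic gates.**  A population of
   20 one-hidden-layer networks (2 inputs → up to 30 hidden units → 1
   output, thresholds realized as bias connections) is trained by
   gradient descent on a gate's truth table (AND or XOR) and evolved
   under the fitness

   *F*<sub>λ</sub>(*G*) = *Q*(*G*) − λσ(*G*),

   where *Q* = 1 − MSE is task fitness and σ is the fraction of
   surviving (nonzero) connections.  At λ = 0 evolution tolerates
   essentially fully connected networks; for mild λ > 0 it converges on
   sparse networks that still implement the gate exactly — parsimony
   pressure recovers the minimal logical structure of the problem.

2. **Genetic programming of a wall-following robot.**  Boolean programs
   over 8 wall-contact sensors (`n ne e se s sw w nw`), 4 move
   indicators (`north east south west`), constants `True`/`False` and
   the primitives `If[·,·,·]`, `&&`, `||`, `!` are evolved by
   wheel-of-fortune selection, subtree crossover and mutation until a
   program is *perfect*: from every free cell of a closed labyrinth it
   reaches the wall and then visits every wall section.

3. **The non-equivalence test.**  A program over 12 boolean variables
   has exactly 2¹² = 4,096 possible input states.  Evaluating two
   champion programs on all of them gives their *truth vectors*; the
   number of states on which the vectors differ measures how far two
   behaviourally indistinguishable champions are from being the same
   boolean function.  The package ships transcriptions of three
   published champion programs (Sol1–Sol3) for this task: Sol2 and Sol3
   disagree on **1,216** of 4,096 states, and Sol1 disagrees with each
   of them on **more than 2,000** states — all three are perfect in the
   labyrinth they were evolved in, so their behaviour outside it is
   essentially unpredictable.

The package is aimed at researchers and students in evolutionary
computation who want a small, fully reproducible testbed for questions
about solution multiplicity, parsimony pressure and generalization.

## Worked example

```python
import numpy as np
from evoequiv import fixtures, gp_engine
from evoequiv.logic_expr import truth_vector, disagreement_count
from evoequiv.reliability import disagreement_matrix

# the three published champions, exhaustively compared
sol1, sol2, sol3 = fixtures.printed_solutions()
report = disagreement_matrix([sol1, sol2, sol3], ["Sol1", "Sol2", "Sol3"])
print(report.to_frame())

# evolve two fresh champions on the closed labyrinth and compare them
closed, _ = fixtures.reference_labyrinths()
a, _ = gp_engine.evolve(gp_engine.GPConfig(seed=0), closed)
b, _ = gp_engine.evolve(gp_engine.GPConfig(seed=1), closed)
print(a.perfect, b.perfect,
      disagreement_count(truth_vector(a.program), truth_vector(b.program)))
```

prints

```
      Sol1  Sol2  Sol3
Sol1     0  2328  2312
Sol2  2328     0  1216
Sol3  2312  1216     0
True True 2128
```

The matrix rows are programs, entries are the number of the 4,096
states on which the two programs' outputs differ (0 would mean semantic
equivalence).  The last line says both freshly evolved champions are
perfect wall-followers on the training labyrinth, yet they disagree as
boolean functions on 2,128 input states — independently evolved perfect
solutions are not equivalent formulations of one another.

A thin CLI wraps the same functionality:

```
evoequiv evolve-gp --seed 0 --out runs/gp0       # champion + history TSV
evoequiv evolve-nn --gate xor --lam 0.1 --out runs/xor01
evoequiv compare --printed                       # the matrix above
evoequiv pipeline --champions 3 --out runs/full  # end-to-end reproduction
```

## Notes on the transcriptions

The packaged `sol1.txt`–`sol3.txt` are careful transcriptions of the
originally printed program listings (see
`src/evoequiv/fixtures.py` for the transcription notes, including the
reconstruction judgment for Sol1's damaged tail).  They are frozen by
checksum in the test suite: editing them without re-verifying the
disagreement anchors fails the tests.
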