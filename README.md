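# mlsel — a multilevel-selection toolkit for cooperation against cheaters

`mlsel` is a simulation and accounting toolkit for studying how cooperation
persists against cheating, for researchers and students in evolutionary
biology and evolutionary game theory. It treats selection as acting on
*entities* at multiple levels — mtDNA molecules, mitochondria, cells,
organisms, interaction groups — and classifies every pro-cooperation
mechanism as **partner choice** (PC: a focal cooperative entity directs more
benefit to cooperative than to cheating partner entities despite their
spatial equivalence) or **partner fidelity feedback** (PFF: lasting
interaction groups whose cooperator frequencies vary stochastically, so
cooperators reap the returns of their own acts).

## The core identity

For a community partitioned into groups, where group *i* starts with
cooperator frequency *P&#7522;* and ends with size *π&#7522;* and frequency *P′&#7522;*, the
Price equation partitions the community-level frequency change:

> π̄ ΔP̄ = Cov(π, P) + Ave(π ΔP),  with Cov(π, P) = β Var(P)

The covariance term (between-group selection) grows with the across-group
variance in cooperator frequency; the expectation term (within-group change)
is typically negative because cheaters win locally. Every model in the
toolkit is an engine for generating — or destroying — that variance:

- **`mlsel.price`** — exact (rational-arithmetic) and floating-point Price
  decompositions of group census tables.
- **`mlsel.group_game`** — a deterministic group-reproduction rule
  ((c, d) → (c², d(2+c))), assortment schemes, group culling, and
  multi-generation community dynamics.
- **`mlsel.toxin`** — toxin–antitoxin suicide cooperation: well-mixed
  episode dynamics with the 1/(1+k) frequency threshold, and a spatial
  lattice where local toxin action rescues rare clustered cooperators.
- **`mlsel.games`** — proportional tit-for-tat (cooperate first, then with
  probability equal to the previous round's fraction of cooperating
  partners) in an iterated public-goods game.
- **`mlsel.mito`** — a nested mtDNA → mitochondrion → cell → organism
  simulator of heteroplasmy dynamics, with every mechanism (replication
  advantage, mitochondrial fitness, selective import, asymmetric
  segregation, mitophagy, apoptosis, germline bottleneck, organism-level
  selection) as a toggleable operator annotated with its entity level and
  PC/PFF class.

## A worked example

```python
from mlsel import GroupComposition, GroupRecord, price_decompose, reproduce_group

g1 = reproduce_group(GroupComposition(1, 5))   # -> 1 cooperator, 15 cheaters
g5 = reproduce_group(GroupComposition(5, 1))   # -> 25 cooperators, 7 cheaters
dec = price_decompose(
    [GroupRecord(6, 1, 16, 1), GroupRecord(6, 5, 32, 25)], exact=True
)
```

Running `python examples/price_decomposition.py` prints:

```
group starting with 1/6 cooperators -> size 16, 1 cooperators (frequency 0.0625)
group starting with 5/6 cooperators -> size 32, 25 cooperators (frequency 0.7812)

mean final group size   pibar   = 24
community freq change   dPbar   = 0.0417
between-group term      Cov     = 2.6667
within-group term       Ave     = -1.6667
identity residual               = 0
```

Cooperator frequency *fell* inside both groups (1/6 → 1/16 and 5/6 → 25/32),
yet the community frequency rose from 1/2 to 26/48: the between-group
covariance term (+8/3) outweighs the within-group decline (−5/3). The other
scripts under `examples/` narrate one capability each (group assortment,
toxin threshold and lattice rescue, the two pTFT requirements, and the
germline mtDNA filter stack).

## Command line

```bash
mlsel price --input groups.csv --out-dir out/
mlsel toxin --c0 210 --d0 40 --out-dir out/
mlsel group-game --config cfg.yaml --seed 1 --out-dir out/
mlsel ptft --config ptft.yaml --seed 1 --out-dir out/
mlsel mito --config mito.yaml --seed 1 --out-dir out/
```

Every stochastic run writes a JSON manifest (parameters, seed, mechanism
annotations, outputs) sufficient to reproduce it bit-for-bit.

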