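# pairbond

Population dynamics of competing male mating strategies in long-lived
primates, built around a 17-compartment ODE model in which males either
**multiply mate** (return to the mating pool after every conception) or
**guard a mate** (form an exclusive pair bond), and females may outlive
their fertility.

The package exists to probe one hypothesis quantitatively: that the
male-biased mating sex ratios produced by a distinct post-fertile female
life stage — a hallmark of human, but not chimpanzee, life history — are
what made mate guarding, and hence pair bonds, the winning male strategy.
It is aimed at researchers in evolutionary ecology and human evolution
who want to simulate the model, map which strategy dominates across
parameter space, and relate the strategy boundary to the adult and
operational sex ratios.

## The model

Seventeen densities are tracked: free fertile females by inherited trait
(`FM`, `FG`), unpaired males by strategy (`M`, `G`), unpaired caring
females by own/dependant trait (`FMm`, `FGg`, `FGm`, `FMg`), pairs of a
guarding male and a female (`PGg`, `PG`, `PMm`, `PMg`, `PM`), post-fertile
females (`X`, `Xm`, `Xg`) and retired males (`Y`). Females conceive at
rate ρ (partner drawn M vs G in proportion to the unpaired pool), care
for each dependant for 1/β years on average, lose fertility at rate
ω_F = 2/(90 − L) (or never, in the no-menopause variant), and die at the
density-dependent rate

    μ_F(t) = max{ 1/L, (β/2) · (sum of the nine carer compartments) },
    μ_M(t) = 1.09 · μ_F(t).

Unpaired males retire at the frailty rate ω_M = 1/(1.6 L). Pair bonds
break at rate χ; a paired paternity is stolen by the multiple-mating pool
with probability q = q\* · M/(M+G). Dependants die at δ_g (guarded) or
δ_m = k·δ_g (unguarded), with δ_g = 0.11/yr from 65% survival to age
four. Sons inherit the father's strategy; daughters carry the sire's
trait.

Running the system to equilibrium and asking which male lineage survives
yields a phase diagram over any two parameters. Two summary ratios are
computed at equilibrium (both counting males per female):

* **OSR** (operational sex ratio) = (M + G) / (FM + FG) — adults
  currently able to conceive;
* **ASR** (adult sex ratio) — all fertile-age adults, paired or not.

The central result the package reproduces: the dominance boundary in
parameter space tracks curves of roughly constant OSR, i.e. the sex
ratio of the mating pool predicts the switch from multiple mating to
guarding.

## Worked example

```python
from pairbond import ParameterSet, find_equilibrium

for label, params in [
    ("chimpanzee-like", ParameterSet(L=22, beta=0.2)),
    ("human-like     ", ParameterSet(L=38, beta=0.25)),
]:
    res = find_equilibrium(params)
    print(f"{label}: dominance={res.dominance.value:15s} "
          f"OSR={res.ratios.osr:6.3f}  ASR={res.ratios.asr:6.3f}")
```

prints

```
chimpanzee-like: dominance=multiple_mating OSR= 7.995  ASR= 0.951
human-like     : dominance=guarding        OSR= 8.406  ASR= 1.276
```

With a 22-year adult lifespan and 5-year interbirth interval the
multiple-mating lineage alone survives; raising the lifespan to 38 years
(and shortening the interbirth interval to 4) leaves many females
post-fertile, pushes the adult sex ratio above 1, and guarding takes
over. The `examples/` directory has one short script per capability —
trajectories, equilibrium classification, phase diagrams with boundary
extraction, and OSR response curves — each printing what the numbers
mean.

A command-line interface mirrors the library for scripted runs:

```sh
pairbond equilibrium -p L=38 -p interbirth_interval=4
pairbond sweep -c run.yaml && pairbond boundary results/ && pairbond plot results/
```

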