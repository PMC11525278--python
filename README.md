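# crxo — optimal design of cluster randomized crossover trials

`crxo` helps trial statisticians plan two-arm **cluster randomized crossover
(CRXO) trials** with a continuous outcome: trials in which intact clusters
(worksites, wards, practices) are randomized to a *sequence* of treatments
over several time periods, so every cluster experiences both conditions and
serves as its own control. The package answers two planning questions:

1. **How many time periods should the trial have?**
2. **Should the treatment switch at every period, or less often?**

both for a fixed number of clusters and under a budget that prices clusters,
subjects and treatment switches.

## Model

For subject *i* in period *t* of cluster *k*,

```
Y_kti = μ + β_t + θ·X_kt + CP_kt + ε_kti
```

with period effects β_t (β₁ = 0), treatment indicator X_kt ∈ {0, 1},
treatment effect θ, random cluster-period effects CP_kt ~ N(0, σ²_CP) with
**exponential-decay** correlation corr(CP_kt, CP_kt′) = r^|t−t′|, and subject
error ε_kti ~ N(0, σ²_ε). Two parameters summarise the correlation
structure: the intraclass correlation ρ = σ²_CP/(σ²_CP+σ²_ε) and the cluster
autocorrelation r. Collapsing each cluster to its T period means gives the
covariance V = (σ²_ε/m)I + σ²_CP·R with R[t,t′] = r^|t−t′|, and with K/2
clusters on a sequence and K/2 on its mirror the GLS covariance of the fixed
effects is

```
var(γ̂) = ( (K/2)·X₁′V⁻¹X₁ + (K/2)·X₂′V⁻¹X₂ )⁻¹ .
```

Its last diagonal entry, **var(θ̂), is the design criterion**: the optimal
design minimises it, and the relative efficiency of any other design ξ is
RE = var(θ̂)_opt / var(θ̂)_ξ. Under a budget B with unit costs c_c (cluster),
c_s (subject) and c_x (switch), a design with S switches affords the largest
even K with `c_c·K + c_s·K·T·m + c_x·K·S ≤ B`.

## Worked example

The packaged defaults describe planning a definitive worksite
sedentary-behaviour trial: ρ = 0.1, r = 0.95, m = 25 subjects per
cluster-period, costs 2500 / 25 / 250 per cluster / subject / switch, budget
250,000. Comparing all eight four-period sequence pairs (each sequence is
paired with its mirror arm):

```console
$ crxo table --t 4 --reference-order
label,sequence,switches,K,cost,re_fixed_k,re_budget
1,AAAA,0,50,250000.0,0.098,0.114
2,BAAA,1,46,241500.0,0.672,0.713
3,BBAA,1,46,241500.0,0.811,0.861
4,BBBA,1,46,241500.0,0.672,0.713
5,ABAA,2,44,242000.0,0.775,0.787
6,AABA,2,44,242000.0,0.775,0.787
7,ABBA,2,44,242000.0,0.985,1.0
8,BABA,3,42,241500.0,1.0,0.969
```

With the number of clusters fixed, the switch-every-period design BABA is
optimal (`re_fixed_k = 1`) and the parallel-group design AAAA would need
roughly ten times the clusters (RE 0.098). Under the budget, switches cost
money: ABBA (two switches, K = 44 affordable clusters) overtakes BABA
(three switches, K = 42), which keeps RE 0.969. Sweeping the number of
periods for alternating designs:

```console
$ crxo sweep --mode budget
label,sequence,T,switches,K,cost,var_theta,relative_efficiency
...
10,ABABABABABA,11,10,20,237500.0,0.001,1.0
11,ABABABABABAB,12,11,18,229500.0,0.001,0.984
```

the optimum sits at T = 11 periods — unlike the fixed-K space, where more
periods always help — and a single design can be priced and powered directly:

```console
$ crxo evaluate --sequence ABBA --k 44 --theta 0.1
{ ... "var_theta": 0.0009333327811895665, "power": 0.90546004288094 ... }
```

i.e. 44 clusters running ABBA/BAAB detect a treatment effect of 0.1 outcome
standard deviations with 91% power at α = 0.05. `crxo simulate` replays any
design through the model-based simulator and checks the analytic variance
against the empirical spread of θ̂; `crxo optimize` reports the best design
in a requested space. All commands accept a YAML scenario file
(`--config`), and the same functionality is available as a library
(`crxo.treatment_variance`, `crxo.sequence_table`, `crxo.period_sweep`,
`crxo.monte_carlo_variance`, …).

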