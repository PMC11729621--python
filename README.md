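# hetmct — multiple contrast tests under partial heteroskedasticity

`hetmct` implements simultaneous inference for linear contrasts of normal
means when the treatment groups are only *partially* heteroskedastic:
treatments fall into prespecified **variance groups**, with equal variances
inside a group and unequal variances across groups. This situation is
common in designed experiments — e.g. a two-factor field trial where only
one factor (here: fungicide spraying technique) drives the variance while
the other (trial location) does not. Assuming full homoskedasticity then
inflates the familywise error rate; assuming complete heteroskedasticity
wastes the within-group replication and costs power.

The package is aimed at biostatisticians analysing one-way or flattened
(cell-means) factorial layouts who would otherwise reach for `multcomp`-style
single-step multiple comparison machinery.

## Model and procedures

Observations follow X_hij ~ N(μ_hi, σ_h²) for variance group h = 1..H,
treatment i = 1..I_h, replicate j = 1..n_hi. The group variances are pooled
as

    S_h² = Σ_i Σ_j (X_hij − X̄_hi)² / Σ_i (n_hi − 1)

and inference targets L contrasts η_l = Σ_hi c_lhi μ_hi with one-sided
hypotheses H0l: η_l ≤ δ_l. The test statistics
T_l = (η̂_l − δ_l) / √(Σ c²_lhi S_h²/n_hi) are referred jointly to central
multivariate t distributions with the estimated correlation matrix
ρ_ll′ = Σ c_lhi c_l′hi S_h²/n_hi / √(v_l v_l′).

Seven single-step procedures are provided, differing in variance source and
degrees of freedom:

| method | variance in T_l and R | degrees of freedom |
|--------|----------------------|--------------------|
| HOM    | single pooled S²     | N − k |
| SDF    | group S_h²           | N − k (manually set residual df) |
| SW     | HC3 sandwich of the cell means | N − k |
| PI     | per-treatment S_hi²  | per-contrast Satterthwaite |
| PIa    | group S_h²           | per-contrast Satterthwaite with S_h² |
| PH     | group S_h²           | partial-heteroskedasticity rule (below) |
| PHmax  | group S_h²           | elementwise max of PIa and PH |

The partial-heteroskedasticity degrees of freedom extend Satterthwaite's
moment matching to whole variance groups: with a_lh = (Σ_i |c_lhi|)² and
N_h = Σ_i n_hi,

    df_l = (Σ_h a_lh S_h²/N_h)² / Σ_h a_lh² S_h⁴ / (N_h²(N_h − I_h)),

so a contrast borrows the replication of every treatment in the groups it
touches (a contrast inside one group gets exactly N_h − I_h). Each T_l is
compared against *its own* equicoordinate critical value
t_{L, df_l, R, 1−α}, giving one-sided adjusted p-values and simultaneous
lower confidence bounds η̂_l − t_{L,df_l,R,1−α}·√v_l with the usual duality
(adjusted p < α ⇔ lower bound > δ_l).

Multivariate t rectangle probabilities are computed by a seeded
Genz–Bretz-type quasi-Monte-Carlo integrator (scrambled Sobol points,
pivoted Cholesky, automatic point-budget escalation) that handles the
singular correlation matrices of all-pairs and each-vs-rest families; see
`docs/methods.md` for numerical details, including why degrees of freedom
are truncated to integers in the multivariate-t evaluation by default.

## Worked example

The bundled summary table from a zearalenone (ZEN, µg/kg) field trial — 15
technique×location cells, variance groups = the five spraying techniques
V1..V5, n = 4 per cell — with the 12 comparisons of each technique against
the untreated control V1, split by location:

```python
import hetmct as hm

stats = hm.mycotoxin_summary()
C = hm.dunnett_by_stratum(3, 5, 1, level_names=["V1","V2","V3","V4","V5"],
                          stratum_names=["Ba","He","Ho"])
res = hm.MultipleContrastTest(stats, C).fit("PH", alpha=0.05, seed=1)
print(res.summary())
```

```
Multiple contrast test: PH (variance source: group)
One-sided greater, familywise alpha = 0.05, L = 12 contrasts

contrast            estimate        se    stat       df    adj p       lower
----------------------------------------------------------------------------
V2-V1:Ba             1468.04    437.47    3.36    10.57   0.0340      105.42  *
V2-V1:He             1675.06    437.47    3.83    10.57   0.0160      312.44  *
V2-V1:Ho             1775.25    437.47    4.06    10.57   0.0112      412.63  *
V3-V1:Ba              493.96    173.68    2.84    17.99   0.0544       -7.32
V3-V1:He               63.56    173.68    0.37    17.99   0.9722     -437.72
V3-V1:Ho              945.70    173.68    5.45    17.99   0.0002      444.42  *
V4-V1:Ba              159.55    168.14    0.95    17.83   0.8058     -325.76
V4-V1:He             -289.28    168.14   -1.72    17.83   1.0000     -774.59
V4-V1:Ho              113.44    168.14    0.67    17.83   0.9103     -371.87
V5-V1:Ba               58.60    157.50    0.37    16.94   0.9714     -399.06
V5-V1:He             -324.60    157.50   -2.06    16.94   1.0000     -782.26
V5-V1:Ho              107.50    157.50    0.68    16.94   0.9079     -350.16

* adjusted p < 0.05
```

Reading: the inoculated control V2 shows clearly higher ZEN than V1 at all
three locations, and the overhead technique V3 does at Hohenschulen
(adjusted p = 0.0002, simultaneous lower bound 444 µg/kg above the
control). Each comparison uses the partial-heteroskedasticity degrees of
freedom (10.57/17.99/…, far above the Satterthwaite-with-group-variance
values 3.52–6.00), which is where the procedure's power advantage comes
from. A starred line is exactly a line whose lower bound exceeds zero.

The same analysis runs from the shell:

```sh
hetmct fixtures mycotoxin --out zen.csv --seed 1
hetmct mct --data zen.csv --contrasts dunnett-by-stratum --strata 3 --levels 5 \
           --methods PH,PIa,PI --seed 1
hetmct simulate fwe --setting d --family tukey --methods PH --reps 10000 --seed 1
```

## Monte-Carlo studies

`hetmct.simulate_fwe` / `hetmct.simulate_power` reproduce the study design
used to validate the procedures: six treatments with mean 100, variance
groups {1,2},{3,4},{5,6}, four allocations (a)–(d) of sample sizes and
standard deviations with total N = 60, contrast families dunnett / tukey /
williams / average / a user-defined two-factor set, one-sided α = 0.05.
Output is a tidy frame (setting, family, method, reps, estimate, mc_se,
seed).

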