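# psindex

Tools for quantifying **parturition synchrony at the individual level**:
how closely one mother's birth date aligns with the birth dates of the
other mothers in her group or population. The package is aimed at
behavioural ecologists and reproductive biologists working with birth
records of mammals (and other viviparous vertebrates), where questions
about maternal quality, social rank, or communal care require a per-mother
synchrony measure rather than a single population-level summary.

## The index

For a group of *N* parturient mothers, let *t<sub>m</sub>* be the relative
parturition date of mother *m* — the number of days elapsed since the
first birth of the season, anchored so the first birth has *t* = 1. The
Parturition Synchrony Index of mother *m* is

```
PSI_m = 1 / ( (1/(N-1)) * Σ_{i≠m} |t_i − t_m|  +  1 )
```

the reciprocal of one plus the mean absolute difference between her date
and every other mother's date. PSI lies in (0, 1]: it equals 1 exactly
when every other mother gave birth on her day, and decays toward 0 as her
date diverges from the group's. The group-level index PSĪ is the
arithmetic mean of the individual values. Because PSI depends only on
pairwise date differences, it is invariant to when in the calendar the
season falls, and an early outlier scores the same as an equally extreme
late one.

The package provides:

* an O(N log N) prefix-sum kernel for the index (groups of thousands of
  mothers are instant), plus a naive double-loop reference;
* a simulator that generates birth-date groups under five season
  distributions (completely synchronous, lognormal, normal, bimodal,
  uniform) across grids of season durations and group sizes, and runs the
  full 168-group robustness study;
* fixed-effects models (one-way and nested ANOVA with LS-means and 95%
  CIs) quantifying how distribution, season duration, and group size shape
  the index and its inter-individual variability (CV);
* CSV I/O for real birth records and a command-line interface.

## Worked example

Three mothers give birth on days 1, 2 and 4 of a season:

```python
>>> import psindex as px
>>> t = px.to_relative_dates([1, 2, 4])
>>> px.psi_all_fast(t)
array([0.33333333, 0.4       , 0.28571429])
>>> px.group_mean_psi([1, 2, 3])
0.43333333333333335
```

The middle mother is the most synchronous (mean distance 1.5 days from
the others, PSI = 1/2.5 = 0.4); the late mother the least (mean distance
2.5 days, PSI = 1/3.5 ≈ 0.286). A census season with one birth per day
({1, 2, 3}) has group mean PSI 13/30 ≈ 0.433.

The same computation from a CSV of birth records (`mother_id,date`, with
integer day numbers or ISO dates, optional `group` column):

```
psindex compute --input births.csv --output psi.csv
```

Running the full robustness study and its analysis:

```
psindex replicate --seed 777 --outdir replication/
```

simulates 168 groups (140,490 mothers), writes the per-mother and
per-group tables, and fits the fixed-effects models. With the default
seed this prints, for group mean PSI,

```
INFO family: F(3,156) = 5.20, p = 0.0019
INFO duration(family): F(16,112) = 216.63, p = 2.51e-76
INFO size(family): F(28,112) = 5.69, p = 1.38e-11
```

with per-family LS-means 0.173 (lognormal), 0.104 (normal), 0.082
(bimodal), 0.067 (uniform): synchrony is highest under a right-skewed
early-season peak and lowest when births are spread evenly, falls sharply
as seasons lengthen, and varies more between mothers (higher CV of PSI)
in longer seasons and smaller groups.

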