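# vegextent

**How far does a pipeline (or road, or railway) disturb the surrounding
plant community — and how do you measure that from a single vegetation
survey?**

`vegextent` implements an indicator-species framework for quantifying
the spatial extent of linear-construction impact on plant communities
from belt-transect surveys.  It is aimed at ecologists and environmental
consultants doing post-construction impact assessment in open
(non-urban) vegetation: you lay belt transects parallel to the corridor
at increasing distances, count stalks and estimate cover in small plots,
and the package turns that survey into an estimated effect extent in
metres.

## The method

For every species *i* and belt transect, the **importance value** is the
mean of three within-transect compositions:

```
IV = (Rd + Rf + Rc) / 3
Rd = d / D     relative density    (stalks of the species / all stalks)
Rf = f / F     relative frequency  (plots occupied / sum over species)
Rc = c / C     relative cover      (species cover / total cover)
```

Species are then classified from their IV profiles across transects by
**modified TWINSPAN** (two-way indicator species analysis): quantitative
profiles are expanded into binary pseudospecies at ascending cut levels,
items are ordered on the first correspondence-analysis axis obtained by
reciprocal averaging, the axis is split at its centroid and the split is
refined with indicator pseudospecies; following Roleček's modification,
the most heterogeneous cluster (mean pairwise Bray–Curtis) is divided
next, so stopping after two breaks yields three clusters.

Each cluster's **integrated importance value** (IIV) — the arithmetic
mean of its members' IVs, absent members counting 0 — is tracked against
distance, and clusters are assigned to response groups:

* **G1** – pioneers: rare originally, dominant near the corridor,
  declining outward;
* **G2** – suppressed original dominants (the *indicator group*):
  depressed near the works, recovering outward;
* **G3** – accompanying species: everything else.

Three distance markers summarize the gradient: **K1** and **K2** are the
distances at which the G1 and G2 trajectories settle into a relative
band around their far-field level (K2, on the indicator group, is the
headline effect extent), and **K3** is the half-open interval between
the last transect where G1 still dominates and the first where G2
overtakes it — the edge-effect transition zone, where richness and
diversity peak and restoration effort matters most.

Diversity indices (Shannon–Wiener *H*, Pielou evenness, Margalef
richness, percent cover) and a seeded permutation correlation test for
validating the indicator group against those indices are included, as is
a synthetic survey generator with known ground truth for end-to-end
verification.  See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

The package ships a reference IV matrix: 8 desert-steppe species
surveyed on 13 belt transects across a three-pipeline corridor (3
working-area and 2 inter-pipeline transects, then 10–1000 m).

```python
import vegextent as vx

table = vx.table1_fixture()
layout = vx.table1_layout()

clustering = vx.modified_twinspan(table.IV, n_clusters=3)
iiv = vx.integrated_iv(table, clustering)
groups = vx.assign_groups(iiv, layout)
est = vx.effect_extent(iiv, groups, layout)
print(groups.mapping, est.K2.K, est.K3.as_tuple())
```

Running `python examples/analyze_reference_survey.py` prints (abridged):

```
Species clusters (dendrogram order):
  1: Achnatherum splendens, Galium verum, Nitraria sibirica
  2: Kalidium foliatum, Scorzonera sinensis
  3: Kalidium gracile, Leymus secalinus, Phragmites australis

Response groups: {'1': 'G3', '2': 'G2', '3': 'G1'}

K2 (effect extent, G2 stabilization): 100 m
K3 (dominance crossover interval):    (50 m, 100 m]
```

Reading: *Phragmites australis* and its companions behaved as pioneers
(dominant in and near the corridor), *Kalidium foliatum* and *Scorzonera
sinensis* are the suppressed original dominants, and the sparse
accompanying species form the third cluster.  Community dominance flips
back to the original dominants between 50 m and 100 m, and the
indicator group's IIV is statistically flat from 100 m outward under the
default 15 % stabilization band.  A wider reading of the same gradient
(folding in diversity evidence) can justify calling the plateau at the
next surveyed belt; the transition-zone note in the report flags exactly
this situation.

`python examples/simulate_and_recover.py` runs the same pipeline blind
on a simulated survey with a known 300 m effect extent and recovers
`estimated K2: 300 m`; `examples/diversity_gradient.py` prints the
per-transect diversity indices.

## Command line

```sh
vegextent simulate --preset s1_like --seed 7 --out-survey s.csv --out-layout l.csv
vegextent report --survey s.csv --layout l.csv --out-dir out/
vegextent report --fixture table1 --out-dir out/   # the packaged matrix
```

`report` chains validate → IV → cluster → classify → extent
(→ diversity) and writes `report.json` plus intermediate CSVs; the
stages are also available as individual subcommands (`validate`, `iv`,
`diversity`, `cluster`, `classify`, `extent`).

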