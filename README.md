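# adscreen

A virtual-screening toolkit for designing dual inhibitors of
acetylcholinesterase (AChE) and beta-secretase 1 (BACE-1), the two central
enzyme targets in Alzheimer's disease drug discovery. It implements, as a
tested and reusable library, the in silico design cascade for curcumin and
flavonoid derivative libraries:

1. **Combinatorial enumeration** — scaffolds with marked attachment points
   ("ports") are decorated with R-groups, exhaustively cycling through all
   combinations at every port, so a scaffold with *n* ports and *r*
   R-groups yields `Σ_{k=1..n} C(n,k)·r^k = (1+r)^n − 1` products.
2. **Drug-likeness filtering** — Lipinski, Ghose, Veber, Egan and Muegge
   rule filters with machine-readable violation reports and a staged
   survivor funnel.
3. **2D descriptors** — MOE-style subdivided surface areas
   (PEOE_VSA±k, SlogP_VSAk, SMR_VSAk), BCUT Burden-matrix eigenvalue
   descriptors, the petitjean shape index, element-distribution entropy
   (a_ICM), reactive-group alerts, an aqueous-solubility estimate (logS)
   and the usual count/property panel.
4. **QSAR prediction** — frozen linear PLS equations for pIC50 against
   AChE (models AT/AF) and BACE-1 (models BT/BF), e.g.

       pIC50(AChE, model AF) = −1.00890 + 2.38027·BCUT_SLOGP_3
                               − 0.11002·reactive − 0.00391·PEOE_VSA+1
                               − 0.00480·PEOE_VSA−3 − 0.00202·SlogP_VSA2
                               − 0.00387·SMR_VSA2

   plus NIPALS PLS refitting, diverse/random 80:20 splitting, and
   IC50 → pIC50 conversion (pIC50 = −log10 IC50 [mol/L]).
5. **Validation arithmetic** — the full external-validation battery for
   regression models (RMSE, R², leave-one-out RMSE/R², R²_pred, Roy's
   rm²/r′m²/r̄m²/Δrm², Lin's CCC, Q_F3²) with the standard pass thresholds
   (rm² ≥ 0.65, CCC ≥ 0.85, r̄m² ≥ 0.5, Δrm² ≤ 0.2, Q_F3² > 0.6), and
   hit-list statistics for pharmacophore screens: %yield, %ratio,
   enrichment factor EF = Ha·D/(Ht·A) and the Güner–Henry goodness-of-hit

       GH = [Ha(3A + Ht)/(4·Ht·A)] · [1 − (Ht − Ha)/(D − A)]

   where D molecules containing A actives return Ht hits of which Ha are
   active (GH = 1 for the ideal model, → 0 for the null model).
6. **Pipeline orchestration** — a deterministic screen runner
   (enumerate → filters → external pharmacophore hit list → QSAR →
   ranking) with a per-stage funnel report and left-joining of external
   (e.g. docking) scores.

A synthetic-data module generates every input class — substituted-aromatic
molecule panels, regression datasets with known coefficients, and
active/decoy screening scenarios — so the entire test suite runs with no
external files or network.

## Port notation

Attachment points are written as atom-mapped dummy atoms in SMILES:
`c1ccc([*:1])cc1` is benzene with port 1. A scaffold may carry any number
of distinct ports, each bonded to exactly one real atom by a single bond;
an R-group carries exactly one (`[*:1]O` is a hydroxyl substituent).
During enumeration an unused port is capped with hydrogen.

## Worked example

```python
from adscreen import parse_molecule, descriptor_vector, load_shipped_models, predict

mol = parse_molecule("COc1ccc(C(=O)/C=C/c2ccc(O)cc2)cc1", "chalcone-1")
models = load_shipped_models()
names = sorted(set(models["AF"].descriptor_names) | set(models["BF"].descriptor_names))
d = descriptor_vector(mol, names)
print(round(predict(models["AF"], d), 2))   # 0.43  (pIC50, AChE)
print(round(predict(models["BF"], d), 2))   # 6.67  (pIC50, BACE-1)
```

The two numbers are predicted pIC50 values (−log10 of the predicted IC50
in mol/L): this chalcone is predicted a micromolar-range BACE-1 binder
(pIC50 6.67 ≈ 0.2 µM) but essentially inactive on AChE under the AF model.

Screening statistics from a hit-count quadruple:

```python
from adscreen import screening_stats

s = screening_stats(D=27024, A=655, Ht=914, Ha=524)
print(round(s.GH, 2), round(s.EF, 2), s.FP)   # 0.62 23.65 390
```

i.e. a screen that recovered 524 of 655 actives among 914 hits from a
27k-compound database has a goodness-of-hit of 0.62 (0.6–0.8 is considered
a very good model) and enriches actives 23.7-fold over random picking.

The same operations are available from the shell:

```bash
adscreen enumerate --scaffolds S.csv --rgroups R.csv -o library.smi
adscreen filter library.smi --rules lipinski,ghose,veber,egan,muegge -o survivors.csv
adscreen predict survivors.csv --model AF --model BF -o predictions.csv
adscreen ghscore -D 27024 -A 655 -Ht 914 -Ha 524
adscreen run --config screen.yaml --out-csv results.csv --out-funnel funnel.json
```

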