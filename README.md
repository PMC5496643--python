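# rxaudit

Co-prescription pattern mining and rational-drug-use auditing for outpatient
prescription records, focused on NSAIDs and gastro-protective agents.

Clinical practice guidelines restrict two common co-prescriptions:

* an **H2-receptor antagonist together with a proton pump inhibitor**
  (e.g. ranitidine + omeprazole) is recommended only for
  gastro-oesophageal reflux disease (GORD, ICD-10 K21.x);
* a **COX-2 inhibitor together with a PPI** (e.g. celecoxib + omeprazole)
  is recommended only for patients at high gastrointestinal risk —
  age ≥ 60 years, a GI complication (ICD-10 K20–K29.9, K30–K38.9,
  K90–K93.8), or aspirin co-therapy.

`rxaudit` detects these patterns in prescription data and audits them.  It
(1) normalises raw hospital drug codes to 4-character compound stems and
groups them into per-visit *transactions* (one patient-day each, visits
with a single study drug excluded), (2) mines association rules with a
from-scratch **Apriori** implementation, and (3) classifies each flagged
visit as guideline-concordant or discordant.

For transactions *P = {P₁…Pₙ}* and disjoint itemsets *X*, *Y*:

* support(X→Y) = P(X ∪ Y)
* confidence(X→Y) = P(Y | X)
* lift(X→Y) = P(X,Y) / P(X)·P(Y) — 1 means independence, >1 a positive
  association

All rule statistics are computed on exact integer counts and rounded
(half-away-from-zero, 4 decimals) only for display.

Real hospital records of this kind cannot be shared, so the package also
ships a synthetic-cohort generator (`rxaudit.synth`) with tunable pairwise
co-prescription structure, plus deterministic fixtures that reconstruct
published summary tables from their rounded statistics via an integer-count
inversion oracle.

## Worked example

Build the packaged 6,168-transaction demonstration fixture and mine it at
the default thresholds (support ≥ 1%, confidence ≥ 50%):

```bash
rxaudit fixture --name table2 --out t2.jsonl
rxaudit mine --input t2.jsonl --out rules.csv
```

```
transactions: t2.jsonl (6168)
12 rules -> rules.csv
```

```
lhs,rhs,support,confidence,lift,support_count
ANTC,OMPZ,0.0113,0.5833,1.0903,70
ARCX,OMPZ,0.0113,0.5833,1.0903,70
ASA.,OMPZ,0.0113,0.5833,1.0903,70
...
```

Exactly 12 single-item rules survive: omeprazole↔ranitidine in both
directions plus ten NSAID/antacid→omeprazole rules.  Each row reads, e.g.:
antacid (ANTC) and omeprazole were co-prescribed in 70 visits (support
0.0113 = 70/6168); 58.3% of antacid visits also carried omeprazole
(confidence); the pair occurs 1.09× more often than independence predicts
(lift).

The full pipeline on a synthetic cohort:

```bash
rxaudit simulate --seed 17 --n-patients 400 --out-dir cohort
rxaudit run --prescriptions cohort/prescriptions.csv \
            --diagnoses cohort/diagnoses.csv \
            --patients cohort/patients.csv --out-dir demo
rxaudit report --run-dir demo
```

```
Association rules
=================
 no. LHS          RHS           support confidence     lift
   1 PRVF         XAND           0.0222     0.5000   1.7857
   2 GAVD         OMPZ           0.0356     0.5714   1.1796
   3 PRVF         OMPZ           0.0222     0.5000   1.0321

Audit: H2RA_PPI (N = 27)
------------------------------
gord:
  GORD                          4 (14.8)
  non-GORD                     23 (85.2)
...
Audit: COX2_PPI (N = 18)
------------------------------
...
discordant:
  yes                           6 (33.3)
  no                           12 (66.7)
```

Of the 1,280 simulated patient-days, 1,055 carried a single study drug and
were omitted, leaving 225 transactions; 27 visits co-prescribed an H2RA
with a PPI (23 without a GORD diagnosis → discordant) and 18 a COX-2
inhibitor with a PPI (6 meeting none of the three risk criteria →
discordant).  `demo/` also holds `transactions.jsonl`, `rules.csv`,
per-pattern findings and summary CSVs, and a `manifest.json` with input
and output checksums; re-running with identical inputs is byte-identical.

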