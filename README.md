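# ucmseg — needs-based population segmentation for regional health systems

`ucmseg` implements a macrosystem population-segmentation cascade of the kind
used by regional population health systems to stratify an entire enrolled
resident population into mutually exclusive, collectively exhaustive (MECE)
needs-based groups, and to test whether those groups are genuinely distinct in
healthcare utilisation, cost and readmission outcomes. It is aimed at health
services researchers and health-system analysts who want a reproducible,
configurable reference implementation of an expert-driven (rule-based)
segmentation model, together with a synthetic administrative-data cohort on
which every stage can be exercised end-to-end.

## The model

Three nested rule-based classifiers operate on routine administrative tables
(resident registry, ICD-10 diagnosis history, encounter-level utilisation, and
emergency admission episodes):

**Lifelong care segments (LS1–LS7).** Each resident is classified once, by
fixed precedence. Let *CFS* be the Clinical Frailty Scale (1–9), *stage* ∈
{none, early, advanced} the chronic-disease stage derived from a 38-condition
ICD-10 catalog (advanced = an advanced-stage marker code or a complication
flag on a matching diagnosis), and *psy* the psychosocial overlay (any
mental-health F00–F99 diagnosis, a medical-social-worker visit, or public
rental housing):

1. CFS > 7 → **LS7** Leaving Well
2. stage = advanced → **LS6** if psy else **LS5**
3. stage = early → **LS4** if psy else **LS3**
4. stage = none → **LS2** if social issues else **LS1** Living Well

**Needs-based sub-segments (A1–A5 / B1–B5).** Residents in LS3–LS6 are
stratified on a stage × complexity matrix: letter A/B = early/advanced stage;
digit 1 = single chronic condition, 2 = multiple conditions, 3 = mental-health
issues, 4 = social issues, 5 = both.

**Episodic care segments (ES1–ES6).** Each emergency admission is classified
from the resident's lifelong segment plus triage acuity (PACS, 1 = most
acute): LS7 → ES6; PACS 3/4 → ES1 (low resource intensity); PACS 2 → ES3 if
the lifelong segment carries a psychosocial overlay (LS2/LS4/LS6) else ES2;
PACS 1 → ES5 if psychosocial else ES4.

All boundaries (frailty cut-off, F-code range, social-issue proxies, the
PACS→acuity mapping, the "multiple conditions" threshold) are configuration,
not code. A Charlson Comorbidity Index (Quan ICD-10 mapping, classic weights)
is computed per resident for the profile tables.

Because the real cohort data are confidential, the package ships a synthetic
cohort generator that plants ground-truth labels, constructs records that
satisfy exactly the planted label's criteria, and calibrates per-segment
outcome distributions to the published per-segment means (annual utilisation
and cost per sub-segment; length of stay, admission cost and 30-day
readmission per episodic segment). The evaluation module reproduces the
per-segment summary tables and the between-segment tests (one-way ANOVA,
Pearson chi-square, OLS trend on segment rank).

## Worked example

```python
import ucmseg as u

cfg = u.default_sim_config(n_residents=5000, seed=42)
bundle = u.generate_population(cfg)
result = u.segment_population(
    bundle.residents, bundle.diagnoses, bundle.encounters, bundle.admissions,
    u.default_catalog(), u.SegmentationConfig(), u.default_cci_table())

print(result.diagnostics["ls_counts"])
# {'LS1': 2092, 'LS3': 1711, 'LS4': 455, 'LS5': 388, 'LS6': 271, 'LS2': 49, 'LS7': 34}

ls_t, sub_t = u.summarise_by_segment(result.lifelong, bundle.residents,
                                     result.profiles, bundle.encounters)
print(sub_t[["segment", "n", "mean_annual_cost", "mean_bed_days"]].round(1))
```

yields the sub-segment utilisation gradient (here for a 5,000-resident draw):

```
segment   n  mean_annual_cost  mean_bed_days
     A1 912            1920.2            0.7
     A2 799            2501.6            0.8
     A3 184            3865.3            1.9
     A4 180            6665.5            4.0
     A5  91            9702.0            8.4
     B1 187            5168.2            3.2
     B2 201            5972.2            3.0
     B3 113            9924.9            8.5
     B4  93           19025.6           10.4
     B5  65           25033.7           23.6
```

Mean annual cost rises monotonically with complexity within each disease
stage (A1→A5 and B1→B5), the qualitative signature the segmentation is
designed to produce; the means fluctuate around the calibrated values (e.g.
SGD 1941 for A1, SGD 23,356 for B5) with sampling error at this cohort size.
Comparing `result.lifelong` with `bundle.truth_lifelong` shows 100% recovery
of the planted labels — the record-construction rules and the classifier are
exact inverses.

The same pipeline is available from the shell:

```bash
ucm simulate --n 5000 --seed 42 --out cohort/
ucm run cohort/ --out results/
```

which writes `assignments_lifelong.csv`, `assignments_episodic.csv`,
`diagnostics.json`, and `report.json` / `report.md` (per-segment profile,
utilisation and episodic outcome tables plus test statistics).

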