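# fmt-rewire

Analysis toolkit for paired donor–patient fecal microbiota transplantation
(FMT) cohorts in inflammatory bowel disease (IBD). It answers the questions a
multi-omic FMT study asks: who responded clinically, how did gut microbial
diversity change, which taxa and metabolites track response, and how much of
the host–microbe–metabolite correlation structure is *rewired* by treatment.

It is aimed at microbiome/metabolomics analysts working with genus-level 16S
relative-abundance tables, absolutely quantified metabolite panels, and
clinical metadata (Mayo score, CDAI, CRP, fecal calprotectin). A synthetic
cohort generator with planted ground truth makes every stage testable without
access to patient data.

## What it computes

**Clinical outcomes.** Week-4 clinical response (UC: partial Mayo reduction
≥ 2 with rectal-bleeding subscore decrease ≥ 1; CD: CDAI decrease ≥ 100),
week-14 clinical remission (UC: partial Mayo < 3; CD: CDAI < 150) and
endoscopic remission (UC: Mayo endoscopic subscore ≤ 1; CD: SES-CD ≤ 2).

**Alpha diversity.** Observed richness, bias-corrected Chao1
S_obs + F₁(F₁−1)/(2(F₂+1)), ACE (Chao & Lee), Shannon entropy −Σ pᵢ ln pᵢ,
and the Simpson index in its dominance form D = Σ pᵢ², so that dysbiosis
reads as *lower* richness and *higher* D. Group contrasts use the two-sided
Mann–Whitney U test (exact for small tie-free samples).

**Response-feature screen.** A taxon or metabolite is FMT-response-associated
when (i) it differs between patient baselines and donors at
Benjamini–Hochberg q < 0.05, (ii) it shifts to donor levels in responders
post-treatment (non-significant vs donors, with the responder-post mean moved
toward the donor mean), and (iii) it persists at baseline levels in
non-responders. FDR is controlled within feature class.

**Ternary networks and rewiring.** Spearman correlation networks over
clinical markers, taxa (prevalence ≥ 60%), and metabolites keep edges with
|ρ| > 0.6 and p < 0.05. Edge counts are censused by class pair, with
metabolite–metabolite pairs excluded from the headline counts. Rewiring is
quantified as edge persistence — the fraction of baseline non-metabolite
edges whose node pair (and sign) recurs post-treatment.

**Multivariate ordination.** PCA with orthonormal loadings, and PLS-DA with
per-feature VIP scores (mean VIP² = 1; VIP > 0.9 flags discriminative
features) and 7-fold cross-validated Q²Y = 1 − PRESS/TSS.

## Worked example

```python
from fmt_rewire import (
    SynthConfig, generate_cohort, screen_response_features,
    build_network, count_class_pairs, edge_persistence,
)

cfg = SynthConfig(n_patients=30, planted_persistence_fraction=0.07, seed=7)
taxa, mets, clin, meta, truth = generate_cohort(cfg)

hits = set()
for tbl in (taxa, mets):
    hits |= set(screen_response_features(tbl, meta).selected_ids)
print(f"screen: {len(hits)} features selected, "
      f"{len(hits & truth.response_feature_ids)} of {len(truth.response_feature_ids)} planted recovered")

net_base = build_network([clin, taxa, mets], meta.baseline_samples())
net_post = build_network([clin, taxa, mets], meta.post_samples(), context="post")
for name, net in (("baseline", net_base), ("post", net_post)):
    c = count_class_pairs(net)
    print(f"{name}: {c['total']} pairs, {c['total_after_exclusion']} after metabolite-metabolite exclusion")
res = edge_persistence(net_base, net_post)
print(f"persistence: {len(res.persisting)}/{len(res.persisting)+len(res.baseline_only)} "
      f"= {res.fraction:.2f} (planted {truth.realized_persistence_fraction:.2f})")
```

Output:

```
screen: 11 features selected, 11 of 12 planted recovered
baseline: 18 pairs, 18 after metabolite-metabolite exclusion
post: 21 pairs, 21 after metabolite-metabolite exclusion
persistence: 1/18 = 0.06 (planted 0.07)
```

The screen recovers 11 of the 12 planted response features with no false
positives here; the rebuilt baseline and post networks recover the planted
correlation pairs, and only 1 of 18 baseline pairs persists post-treatment —
close to the 7% persistence planted in the generator, i.e. the networks are
almost completely rewired.

The same stages are available from the shell:

```sh
fmt-rewire run --out myrun --seed 7           # full pipeline with report.json
fmt-rewire simulate --out cohort --seed 7
fmt-rewire outcomes --table outcomes.csv --cohort UC
fmt-rewire network build --taxa cohort/taxa.tsv --metabolites cohort/metabolites.tsv \
    --clinical cohort/clinical.tsv --meta cohort/metadata.csv --out net.graphml
```

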