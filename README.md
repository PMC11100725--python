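# secom

Single-cell super-enhancer (SE) community analysis for multiplexed
DNA-FISH spot tables: contact and community calling from per-cell 3D
localizations, uniform-random null simulation, partner-entropy /
cooperativity / odds-ratio statistics, transcription-burst coupling,
per-SE genomic feature extraction, and shallow-network prediction of
community size. A synthetic-data generator replaces the imaging dataset
so the whole pipeline is testable offline.

## Layout

| module | purpose |
| --- | --- |
| `secom.locus_model_io` | SE locus tables (BED-like), spot tables (flat TSV and FOF-CT-style dialects), core data model |
| `secom.registration` | mutual-NN pair matching, 2nd-order 3D chromatic warp, allele assignment, detection efficiency, replicate error |
| `secom.simulate` | uniform-nucleus null, diploid territory model with attractor nucleation, detection dropout + localization noise, calibrated burst model, synthetic feature tracks |
| `secom.proximity` | per-cell distance maps, neighbor counts, cluster/community-size profiles, pairwise contact frequencies, threshold sweeps |
| `secom.interaction_stats` | partner distributions and Shannon entropy, triplet catalogs, cooperativity (observed/expected), odds ratios, contact-map correlation |
| `secom.expression_coupling` | punctum-to-allele burst association, burst-vs-community coupling, OR by community size, conditional distance maps, co-bursting |
| `secom.feature_tracks` | bedGraph coverage, DamID window scores, SPRITE speckle association, genomic tether metrics, feature-table assembly |
| `secom.community_predictor` | 10-node single-hidden-layer regressor with replicate 75/25 splits and feature-subset ablation |

Conventions: genomic intervals 0-based half-open (bp), spatial
coordinates in nanometers, undetected spots carry NaN coordinates.
Cluster size at radius r is the star count (1 + other spots strictly
within r); contacts use 200 nm, communities 600 nm by default.

## CLI

```sh
secom simulate --config sim.yaml --seed 1 --out spots.tsv     # synthetic spot table
secom register --spots spots.tsv --out detection.tsv          # detection efficiency
secom cluster  --spots spots.tsv --radius 600 --out prof.tsv  # cluster-size profile
secom stats    --spots spots.tsv --out entropy.tsv            # partner entropy
secom express  --bursts bursts.tsv --out or.tsv               # OR by community size
secom predict  --features f.tsv --target t.tsv --out rep.tsv  # NN regression
secom tracks   --loci loci.tsv --track pol2 p.bedgraph --out features.tsv
```

`sim.yaml` keys mirror `secom.simulate.SimConfig`
(e.g. `n_cells`, `n_points`, `nucleus_radius`, `detection_eff`).

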