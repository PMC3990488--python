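# rsatools

Representational similarity analysis (RSA) in Python: characterize
multichannel activity patterns by representational dissimilarity matrices
(RDMs), visualize and summarize representational geometry, and statistically
relate brain RDMs to model RDMs with nonparametric inference.

Features:

- **RDM computation** (`rsatools.rdm`) — correlation, Euclidean, and
  Mahalanobis dissimilarities from condition × channel pattern estimates;
  rank / z / percentile transforms; averaging. The canonical vector layout is
  the upper triangle, row-major, diagonal excluded.
- **RDM comparison** (`rsatools.compare`) — Pearson, Spearman, and Kendall's
  τ_A (the proportion of consistently ordered pairs; ties count in the
  denominator only), with an O(n log n) merge-sort implementation
  cross-checked against an O(n²) enumeration oracle; RDM-by-RDM correlation
  matrices.
- **Noise ceiling** (`rsatools.ceiling`) — upper bound from the overfitted
  central RDM (z-mean for Pearson, rank-mean for Spearman, rank-mean plus
  iterative refinement for τ_A), lower bound by leave-one-subject-out.
- **Inference** (`rsatools.inference`) — default test selection (signed-rank
  across subjects from 12 subjects; stimulus-label randomization + stimulus
  bootstrap from 20 conditions otherwise), one-sided signed-rank relatedness
  tests, exhaustive/sampled label randomization, bootstrap candidate
  comparison over stimuli and/or subjects, Benjamini–Hochberg FDR and
  Bonferroni FWE control.
- **LD-t** (`rsatools.ldt`) — the crossvalidated linear-discriminant t:
  Fisher discriminant fit on one partition, t value of the projected
  contrast on the other; full LD-t RDMs averaged over both fold directions.
- **Searchlight** (`rsatools.searchlight`) — spherical in-mask neighborhoods
  (anisotropic voxel sizes honored), per-voxel model-correlation maps,
  group-level signed-rank + FDR inference.
- **Simulation** (`rsatools.simulate`) — patterns driven by pairwise forces
  to conform to a target RDM, noisy per-subject replicates, GLM-style fMRI
  time series (Y = XB + E with HRF-convolved designs and smoothed noise),
  and a ready-made simulated group scenario with categorical candidate
  models.
- **Geometry** (`rsatools.geometry`) — metric-stress MDS arrangements and
  hierarchical cluster trees (optional Newick export).
- **I/O + CLI** (`rsatools.io`, `rsatools.cli`) — CSV for single objects,
  HDF5 for collections, NIfTI for volumes; a unified `rsa` command with
  provenance logging.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the package
invariants, and `tests/test_acceptance.py` with the end-to-end acceptance
criteria (simulated group scenario, calibration of all tests, searchlight
planted-region recovery). The full run takes a few minutes on one CPU.

## CLI

```bash
# simulate a group scenario and run the full inference workflow
rsa simulate fig4 --seed 1 --out scenario
rsa infer --reference scenario_subjects.h5 --candidates scenario_models.h5 \
    --method tau-a --mc fdr --alpha 0.05 --seed 1 --out result.json

# individual steps
rsa compute-rdm patterns.csv --measure correlation --out rdm.csv
rsa compare --method tau-a rdm1.csv rdm2.csv
rsa ceiling --method tau-a scenario_subjects.h5
rsa mds rdm.csv --out coords.csv
rsa cluster rdm.csv --linkage average --out tree.json --newick tree.nwk
rsa ldt --partitions partitions.h5 --out ldt_rdm.csv
rsa searchlight --data sub01.nii --data sub02.nii ... --mask mask.nii \
    --model model.csv --radius 7 --out-prefix sl
```

Every CLI run writes a `<out>.provenance.json` recording the configuration,
seed, and package version, so analyses replay exactly.

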