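# codahd

Compositional data analysis for high-dimensional, sparse single-cell
RNA-seq count matrices. The package treats each cell's gene counts as a
composition and works with log-ratio representations instead of
log-normalized absolute values:

- **Count-addition schemes** that make sparse counts log-safe: per-cell
  offsets proportional to library size (`s10000`, `smax`, `sgm`) as well
  as plain constant addition and half-minimum zero replacement (kept for
  comparison; not recommended).
- **Log-ratio transforms**: centered log-ratio (CLR), isometric
  log-ratio (ILR, pivot coordinates), housekeeping-gene log-ratio
  (HKGLR), and CLR obtained directly from *already log-normalized* data
  (`clr_from_lognorm`), which is elementwise identical to CLR with the
  `S/10000` offset — so public log-normalized matrices can be carried
  into the log-ratio framework without raw counts.
- **Dimension reduction**: per-gene centering + truncated (Lanczos) SVD,
  with an exact full-SVD log-ratio analysis (`lra_exact`) as oracle.
- **QC**: minimum detected-gene filtering, MAD-based outlier removal on
  counts/features/mitochondrial fraction, gene-prevalence filtering, and
  highly-variable-gene selection.
- **Evaluation metrics**: entropy of accuracy/purity, ARI, NMI, Spearman
  pseudotime correlation, pairwise ordering score (POS), lineage branch
  matching with overlap/false rates, and rank-based marker AUROC with a
  non-marker false-positive control.
- **Simulation**: a gamma-Poisson generator with per-group DE factors,
  log-normal library sizes and logistic dropout, returning both the
  observed and the pre-dropout ground-truth matrices; plus a degraded
  cell spike-in procedure (copy cells, zero a fraction of genes).

All transforms are computed sparsity-aware in log space: per-cell
geometric means cost `O(nnz + N)` and restricting CLR output to a gene
subset never materializes a dense genes × cells intermediate. The CLR
denominator always runs over **all** genes, even when the output is
restricted to a subset.

## Quick start

```python
import codahd as ch

X = ch.read_counts("path/to/10x_dir")          # or a genes x cells CSV
X, report = ch.filter_cells(X, ch.QCParams())
X = ch.filter_genes(X, ch.QCParams())

M = ch.clr(X, ch.CountAdditionScheme.sgm())    # SGM count addition + CLR
hvg = ch.select_hvg(M, 3000)
E = ch.pca_truncated(M.subset_components(hvg), k=10, seed=7)
labels = ch.cluster_cells(E, n_clusters=5, algorithm="kmeans", seed=7)
```

From already log-normalized data:

```python
M = ch.clr_from_lognorm(ch.lognormalize(X))    # == ch.clr(X, s10000)
```

## CLI

```sh
codahd simulate --n-genes 10000 --n-cells 1500 --seed 42 --out sim/
codahd transform --input sim/counts --scheme sgm --lr clr --hvg 3000 \
    --pcs 10 --seed 7 --out out/
codahd run --input sim/counts --truth sim/groups.csv --lr clr \
    --scheme sgm --seed 7 --out run/        # QC -> CLR -> HVG -> PCA ->
                                            # k-means -> metrics + deltas
codahd spike-degraded --input sim/counts --labels sim/groups.csv \
    --target-type Group1 --out spiked/
codahd eval-clustering --labels pred.csv --truth truth.csv
codahd eval-trajectory --pseudotime pt.csv --truth time.csv
codahd eval-markers --matrix clr.csv --labels types.csv \
    --positive-type T1 --degs degs.txt --nondegs nondegs.txt
```

`codahd run` writes the transformed matrix, the embedding, cluster
labels, and a JSON run log (parameters, seed, per-file checksums). When
truth labels are given it also runs the log-normalization baseline under
the same protocol and reports per-metric deltas where positive always
means improvement.

## Tests and acceptance

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes, from scratch: the lognorm→CLR
equivalence identity, the truncated-SVD vs exact-LRA agreement, the
multi-seed directional benchmarks (SGM-CLR vs constant-addition CLR vs
log-normalization for clustering and degraded-cell separation), and the
branch-matching worked example. No numeric acceptance targets are
defined for this artifact, so the JSON report is an empty object; the
computed quantities are printed to stdout.
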