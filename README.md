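# chd — connectome-harmonic decomposition

`chd` is a Python library and CLI for analysing brain activity in the basis of
**connectome harmonics**: eigenmodes of the symmetric normalized graph
Laplacian of a vertex-level structural connectome. It covers the full
workflow:

- **Graph construction** — combine a cortical surface mesh (local edges =
  shared triangle edges) with long-range fiber endpoint pairs into a binary
  adjacency matrix; average graphs across subjects; prune isolated vertices.
  Synthetic connectomes (two icosphere hemispheres plus distance-decayed
  long-range edges) are first-class citizens for testing.
- **Harmonics** — eigenpairs of `D^{-1/2}(D − A)D^{-1/2}` (eigenvalues in
  [0, 2]), dense for small graphs, shift-invert Lanczos for partial spectra,
  with a deterministic sign convention and residual checks.
- **Decomposition** — project vertex×time functional data onto the basis
  (`α_k(t) = ⟨F_t, ψ_k⟩`), with power `|α|` and energy `|α|²λ²` tensors
  satisfying Parseval's identity and `Σ_k E(k,t) = ‖ΔF_t‖²` exactly.
- **Analyses** — log-spaced (15-level) energy spectra with paired
  permutation + Bonferroni contrasts; repertoire distributions normalized by
  the baseline per-harmonic maximum with Gaussian width fits; total-energy
  probability distributions and characteristic energy; cross-frequency
  correlation matrices with band summaries, 10×10 partition means and Cohen's
  d contrasts; power-law fits (100-bin logarithmic binning, OLS in
  log10–log10, exponent β and RMSE ε) with per-subject t-test comparisons;
  multiple correlation (direct and harmonic-mediated).
- **Synthetic functional data** — scans with known ground-truth coefficients,
  power-law spectral profiles, band modulations, within-band coupling, and a
  paired two-condition study generator with planted effects.

## CLI

```bash
chd synth-graph --order 2 --long 200 --seed 1 --out graph.mtx
chd build-graph --mesh L.off --mesh R.off --long-edges edges.tsv --out graph.mtx
chd harmonics --graph graph.mtx --modes all --out basis.h5
chd decompose --basis basis.h5 --func scan.tsv --out coeffs.h5 [--zscore]
chd simulate --basis basis.h5 --subjects 12 --timepoints 100 --seed 1 --out data/
chd spectra --coeffs s1.h5 --coeffs s2.h5 --basis basis.h5 --baseline A --out spectra/
chd crossfreq --coeffs coeffs.h5 --partitions 10 --out xf/
chd criticality --coeffs s1.h5 --coeffs s2.h5 --bins 100 --out fits.tsv
chd run --config study.yaml --out results/
```

File formats: meshes as ASCII OFF/PLY; adjacency as Matrix Market (`.mtx`);
long-range edges as 2-column TSV with a `# n_vertices=<n>` header; functional
data as TSV (vertices × time, `#`-header with n/T/TR); bases and coefficients
as HDF5 containers with JSON provenance sidecars.

## Layout

```
src/chd/
  mesh.py           # SurfaceMesh, icosphere generator, OFF/PLY I/O
  connectome.py     # adjacency construction, averaging, pruning, synthesis
  harmonics.py      # Laplacian, eigensolver, basis persistence
  decomposition.py  # projection, reconstruction, power/energy, z-scoring
  spectral.py       # binned spectra, repertoire/energy distributions, contrasts
  crossfreq.py      # cross-frequency matrices, bands, partitions, effect sizes
  criticality.py    # log binning, power-law fits, condition comparison
  stats.py          # t/KS/permutation tests, Bonferroni, Cohen's d, multiple R
  synth.py          # synthetic functional series and study designs
  pipeline.py       # end-to-end orchestration with manifests
  cli.py            # `chd` entry point
```
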