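# fragseq

Spatial niche reconstruction and niche-resolved statistics for
**fragment-based single-cell transcriptomics**.

## The problem

Dissociating a tissue for scRNA-seq destroys every cell's spatial context.
Fragment-based protocols recover part of it: tissue is *partially*
dissociated into Ø 200–450 µm multicellular fragments, each fragment is
sorted into its own well with a large-particle biosorter, dissociated to
single cells, hashed with a fragment-specific lipid-anchored DNA barcode,
and pooled for scRNA-seq. Each cell's fragment of origin — its local
neighborhood of tens of cells — is then recoverable from the hashing
counts, without ever assigning physical coordinates to a cell.

The fragment becomes the unit of spatial analysis. In the liver, a
fragment's position along the central–portal lobule axis is reconstructed
from landmark genes; in a metastasis-bearing liver, fragments are grouped
by whether they contain metastatic cells. `fragseq` implements this
computational workflow end to end, together with a synthetic-data generator
that reproduces its statistical structure with known ground truth.

## The core quantities

**Zonation coordinate.** For each fragment, pseudobulk expression over its
liver endothelial cells is max-normalized per gene across fragments, summed
over portal (pLM) and central (cLM) landmark genes, and combined as

```
ZC_raw = pLM / (pLM + cLM)
ZC     = (ZC_raw − min ZC_raw) / (max ZC_raw − min ZC_raw)
```

so 0 is the most pericentral and 1 the most periportal fragment. Rescaled
ZCs are binned into lobule layers L1…L10 (deciles; sparse extremes merged
into L1–L3 and L8–L10) and grouped into pericentral (L1–L5) and periportal
(L6–L10) zones.

**Niche statistics.** Zonated genes are detected per gene with a negative
binomial log-linear model on fragment pseudobulks, the lobule layer
entering as an ordered factor (L1–L3 < L4 < L5 < L6 < L7 < L8–L10) and
samples as fixed-effect blocks; Benjamini–Hochberg controls the FDR.
Cell-type abundance shifts between niches use the same model on
sample × group cell counts with a total-cells offset. Ligand–receptor
interactions between two clusters are scored as the mean of ligand (sender)
and receptor (receiver) normalized expression — complexes summarized by
their limiting subunit — with one-sided p-values from cluster-label
permutations, `p = (b+1)/(m+1)`. For imaging-based validation data, a
radius neighbor graph (edge iff distance < 10 µm) yields normalized
type–type edge counts per ROI, and group differences are tested by
permuting vertex labels per slide.

Supporting stages: DNA hashing-barcode design under a minimum pairwise
Hamming-distance constraint, POSITIVE/NEGATIVE/DOUBLET cell classification
from barcode counts, species-mixing accuracy scoring, biosorter
TOF-to-size calibration and gating, segment-label expansion, transcript
assignment, MAD-based segment filtering and polygon area annotation.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/02_zonation_reconstruction.py
fragments placed: 174 (>=5 LECs each)
Spearman(ZC_est, ZC_true) = 0.997
fragments per zone: {'central': 94, 'portal': 80}
       zc_raw  zc_rescaled layer     zone
F0001   0.475        0.472    L5  central
F0002   0.843        0.951   L10   portal
...
```

200 simulated fragments with 20 + 20 landmark genes and negative binomial
noise are placed on the lobule axis; the Spearman correlation of 0.997 with
the simulator's hidden true coordinates shows the landmark reconstruction
essentially recovers the spatial ordering. Downstream:

```bash
$ python examples/03_zonated_genes.py
genes tested: 71   significant at FDR<0.05: 43
planted gene: coef=+0.131 per layer level, p=8.03e-34, FDR=1.39e-33
```

The planted portal gene is recovered with a positive layer-trend
coefficient (expression rising toward the portal pole). The other examples
demultiplex hashed cells (01), test niche cell-type abundance (04), rank
ligand–receptor interactions between niches (05), run the colocalization
permutation test (06) and calibrate fragment size from sorter TOF (07).

A thin CLI covers orchestration: `fragseq simulate`, `fragseq zonate` and
`fragseq run --config cfg.yaml` (full pipeline with a hashed output
manifest; identical config and seed give byte-identical outputs).

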