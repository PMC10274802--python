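# ahntools

Analysis toolkit for the circuits of the ascending histaminergic neurons
(AHNs) of the fly ventral nerve cord (VNC) — two bilateral pairs (MsAHN,
MtAHN) that carry motor-related signals from the VNC to the brain, a
candidate corollary-discharge pathway. The package implements the
quantitative pipeline used to characterize such neurons from EM
connectomes, single-cell transcriptomes and calcium imaging:

- **Partner demographics.** Synapse-count thresholding of connectome
  edges, rescaling of a threshold between EM volumes of different
  reconstruction completeness, synapse fractions by partner cell class,
  descending-neuron (DN) type summaries with a pooled remainder, and
  partitioning of upstream partners by which focal cells they contact
  (shared-input graphs).
- **Effective connectivity.** Type-collapsed connectivity, input
  fractions, and path-length-2 effective connection strength
  E(s,t) = Σₘ F(s→m)·F(m→t), where F(g→h) is the fraction of group h's
  total synaptic input contributed by group g and the sum runs over
  intermediaries m that are neither descending nor sensory, nor the
  source/target groups themselves.
- **Morphology matching.** SWC skeleton handling, rescaling to microns,
  fixed-point pruning of terminal twigs < 10 μm, reduction to dotprops
  (points + local principal-direction tangents), and NBLAST-style
  scoring: for each query point, the nearest target point contributes a
  log-odds score S(distance, |tangent·tangent|); scores are normalized
  by the query self-score and ranked.
- **Transcriptome filter.** Candidate-AHN selection from raw counts
  (Hdc ≥ 2 and exactly one of Antp/Ubx ≥ 2 with ≥ 15:1 dominance),
  CPM-log2 normalization, and complete-linkage Euclidean clustering of
  gene panels with canonical tie-breaking.
- **Calcium traces.** Frame-wise background subtraction, 5-s
  pre-stimulus baseline ΔF/F, and per-group trace aggregation.
- **Synthetic data.** Seeded generators that plant exactly the structure
  the analyses assume — convergent common-input DNs, a
  focal → interneuron → motor-neuron chain per pair, exact-length
  skeleton twigs, marker-gene cells, stimulus-locked transients — and
  return the ground truth for recovery tests.

Two published summary tables ship as packaged fixtures: the per-cell AHN
connectivity summary across the FANC, MANC and FAFB volumes
(`ahntools.data.connectivity_summary()`) and the candidate-AHN cells of
the adult VNC single-cell atlas (`ahntools.data.candidate_cells()`).

## Worked example

Rescaling the partner-inclusion threshold between nerve-cord volumes:
the female VNC (FANC) analyses use a 3-synapse threshold, and the male
VNC (MANC) reconstruction recovers more synapses per neuron, so the
threshold is rescaled by the ratio of total AHN connection counts:

```python
>>> from ahntools.data import manc_thresholds
>>> manc_thresholds(base_threshold=3)
(10, 3)
```

The upstream threshold becomes 10 (ratio 13481/4114 ≈ 3.28, times 3,
rounded); the downstream ratio is ≈ 1.09, so the threshold stays 3.

Planted-structure recovery on a synthetic connectome:

```python
>>> from ahntools.synth import ConnectomeSpec, gen_connectome, MN_GROUP_NAMES
>>> from ahntools import demographics as dg, effective as ec
>>> table, edges, sites, gt = gen_connectome(ConnectomeSpec(seed=5))
>>> kept = dg.apply_threshold(edges, 3, set(gt.focal_ids))
>>> part = dg.partition_shared_input(kept, gt.focal_ids, table)
>>> set(part.common_to_all) == set(gt.common_input_ids)
True
>>> grouping = {r.neuron_id: (r.type_label or r.cell_class.value) for r in table}
>>> fr = ec.to_input_fractions(ec.collapse_by_group(edges, grouping))
>>> gclass = {grouping[r.neuron_id]: r.cell_class for r in table}
>>> eff = ec.effective_strength(fr, ["MsAHN", "MtAHN"],
...                             ["MN_wing", "MN_leg"], gclass)
>>> eff.matrix.round(3)
       MN_wing  MN_leg
MsAHN    0.402   0.149
MtAHN    0.100   0.474
```

The 30 planted common-input DNs are recovered exactly, and each pair's
2-step effective strength peaks on its own planted motor-neuron group
(wing for the mesothoracic pair, leg for the metathoracic pair) — the
segregated-output structure the analysis is designed to expose.

The same operations are scriptable via the `ahntools` CLI
(`synth`, `demo`, `effconn`, `morph`, `tx`, `traces` subcommand
families); run `ahntools --help`.

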