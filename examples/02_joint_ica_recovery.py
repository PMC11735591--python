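"""Fit joint ICA and score it against the planted ground truth.

The decomposition concatenates variance-balanced GM and WM blocks, unmixes
with FastICA, and splits the sources back per modality. Hungarian matching
of loading columns then shows how well each planted source was recovered.
"""

from jointica import SimConfig, generate_dataset, jointica_fit, match_components

dataset, truth = generate_dataset(SimConfig(k_sources=4, seed=7))
dec = jointica_fit(dataset.gm, dataset.wm, n_components=4, seed=7)
print(f"FastICA converged: {dec.converged} after {dec.n_iter} iterations")

report = match_components(truth, dec)
print(report.to_frame().round(4).to_string(index=False))
print(f"mean |corr|: loadings {report.mean_loading_corr:.4f}, "
      f"GM sources {report.mean_gm_source_corr:.4f}, "
      f"WM sources {report.mean_wm_source_corr:.4f}")
# Values near 1 mean the shared loading matrix and both modality patterns of
# every planted source were recovered almost exactly at SNR 5.
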