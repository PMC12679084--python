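"""Rank candidate scavengers over the 100/400/500/1,000 µM dose grid.

Screens a 12-compound panel spanning weak to strong latent potency and
prints the top hits; rank 1 should be the truly most potent candidate at
one of the higher doses.
"""

from mgoscav import deepmodel, screening, synthdata, workflows

study, compounds, truth, config = workflows.emulation_study(
    seed=5, n_compounds=150, records_total=600,
    train_config=deepmodel.TrainConfig(epochs=60, seed=5),
)

panel, pick = synthdata.screening_panel(compounds, truth, n_panel=12)
result = screening.screen_compounds(study.trained, panel)  # default grid + cutoff -0.186

print(result.rows.head(6).to_string(index=False))
top = result.rows.iloc[0]
print(f"\nrank 1: {top.compound_id} at {top.concentration_uM:g} µM, score {top.score:.3f}")
print(f"ground truth most potent panel member: {panel.compound_ids[-1]}")
print("rows are (compound, dose) pairs ranked by predicted score; 'active'")
print("flags scores strictly above the -0.186 cutoff.")
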