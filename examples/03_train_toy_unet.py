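"""Train the 3D U-Net on phantoms and segment a held-out study.

Uses the desk-scale toy configuration (2 resolution levels, width 8,
200 iterations per epoch, 10 epochs) on 8 training + 2 validation phantoms.
Takes a few minutes on one CPU.  The printed per-epoch log shows the
cross-entropy loss falling and the validation aorta Dice climbing past 0.85;
the best-Dice checkpoint is what the pipeline would deploy.
"""

import noisekit as nk

cohort = nk.generate_cohort(10, seed=7)
model = nk.train(cohort[:8], cohort[8:], nk.TrainingConfig.toy(seed=7))

for row in model.training_log:
    print(f"epoch {row['epoch']}: train loss {row['train_loss']:.3f}, "
          f"val loss {row['val_loss']:.3f}, "
          f"val aorta Dice {row['val_dice_aorta']:.3f}, lr {row['lr']:.1e}")
print(f"best validation aorta Dice: {model.best_val_dice['aorta']:.3f}")

# segment the first validation phantom and measure through the prediction
pred = nk.postprocess(nk.sliding_window_infer(model, cohort[8].volume))
d = nk.dice(pred, cohort[8].labels, "aorta")
print(f"aorta Dice on a held-out phantom after postprocessing: {d:.3f}")
print("The aorta is learned quickly; the thin coronary tubes need a longer")
print("schedule, which is why measurement tests drive the pipeline with")
print("ground-truth masks at desk scale.")
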