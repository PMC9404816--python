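"""Train the network on synthetic data at reduced scale and score a holdout.

Runs the standard scaled-down experiment: 30 easy-contrast 64x64 images,
fourfold augmentation of the 24 training images, 10 epochs of Adam at 5e-4.
Takes a couple of minutes on one CPU.  The held-out Dice coefficient shows
how well the four decoders recover the joint-threshold masks of images they
never saw.
"""

from tangleseg.experiments import scaled_learning_check

result = scaled_learning_check(seed=1)

print(f"training loss: {result.first_epoch_loss:.4f} (epoch 1) -> "
      f"{result.final_epoch_loss:.4f} (epoch {len(result.loss_history)})")
print("held-out means over", "6 images x 4 outputs:")
for metric in ("dc", "iou", "tp", "fp"):
    print(f"  {metric.upper():<4} {result.holdout_mean[metric]:.4f}")
print("\nDC near 1 and FP near 0 mean the predicted masks closely match the"
      "\nground-truth channel-combination masks on unseen images.")
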