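"""Fine-tune the tiny dual encoder on curated phantom pairs.

A randomly initialized linear dual encoder is evaluated on held-out
findings, trained with the symmetric contrastive objective (cosine-
annealed AdamW, min-validation-loss checkpoint), and evaluated again.
"""

from keyslice.pipeline import finetune_experiment

result = finetune_experiment(seed=0)

print(f"eval findings:        {result['n_eval_findings']}")
print(f"Top-1 before training {result['top1_before']:.1f}%")
print(f"Top-1 after training  {result['top1_after']:.1f}%")
print(f"gain                  {result['gain_points']:+.1f} points")
print(f"val loss {result['val_loss_initial']:.3f} -> {result['val_loss_best']:.3f} "
      f"(best epoch {result['best_epoch']})")
# Training aligns organ sentences with the slices that contain those
# organs; the Top-1 gain is the desk-scale analogue of the accuracy
# improvement that fine-tuning yields for pretrained backbones.
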