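"""The three evaluation metrics and the training loss on small hand masks."""

import numpy as np

from ghdcnet.metrics import assd, combined_loss, dice, miou

truth = np.zeros((10, 10), dtype=np.uint8)
truth[3:7, 3:7] = 1  # a 4x4 lesion
pred = np.zeros((10, 10), dtype=np.uint8)
pred[3:7, 4:8] = 1   # the same lesion, one pixel to the right

print(f"Dice  = {dice(pred, truth):.4f}   (overlap: 12 shared of 16+16 pixels)")
print(f"mIoU  = {miou(pred, truth):.4f}   (mean of lesion and background IoU)")
print(f"ASSD  = {assd(pred, truth):.4f} px (average boundary-to-boundary distance)")

# the training objective on soft predictions: cross-entropy + soft Dice
half_sure = np.where(truth == 1, 0.5, 0.0)
print(f"loss at p=0.5 on the lesion = {combined_loss(half_sure, truth):.4f} "
      f"(BCE term ~{np.log(2) * 16 / 100:.4f} + soft-Dice term 1/3)")
perfect = truth.astype(float)
print(f"loss at perfect prediction  = {combined_loss(perfect, truth):.6f}")
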