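"""Gradient-weighted class activation mapping on 1-D spectra.

The attribution target is the output of the last (fifth) convolutional
block.  Channel weights are the position-averaged gradients of the class
logit with respect to that feature map; the CAM is the rectified weighted
channel sum, linearly interpolated back onto the 801-point wavelength grid
and max-normalised to [0, 1].

The class-average protocol mirrors the study workflow: attribute the mean
spectrum of a class only when the classifier actually predicts that class
for it — a mispredicted average spectrum yields a refusal, not a curve,
because the attribution would explain the wrong decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .cnn import CNNResults
from .grid import CANONICAL_GRID, Spectrum, SpectraSet, WavelengthGrid

__all__ = ["AttributionCurve", "CamRefusal", "grad_cam", "cam_for_class"]


@dataclass
class AttributionCurve:
    """Per-wavelength importance in [0, 1] for one class."""

    grid: WavelengthGrid
    importance: np.ndarray
    class_id: int
    source: str = "single_spectrum"   # or "class_average"
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.size != self.grid.n_points:
            raise ValueError("importance length must match the grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.importance))])

    def band_mass(self, center_nm: float, half_width_nm: float) -> float:
        """Sum of importance inside center +- half_width."""
        wl = self.wavelengths
        mask = np.abs(wl - center_nm) <= half_width_nm
        return float(self.importance[mask].sum())

    def to_csv(self, path) -> Path:
        path = Path(path)
        data = np.column_stack([self.wavelengths, self.importance])
        header = "wavelength_nm,importance"
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.10g")
        return path


@dataclass
class CamRefusal:
    """Returned when the class-average spectrum is mispredicted."""

    class_id: int
    predicted_class: int

    @property
    def refused(self) -> bool:
        return True


def grad_cam(results: CNNResults, x: Union[Spectrum, np.ndarray],
             class_id: int, source: str = "single_spectrum") -> AttributionCurve:
    """Grad-CAM attribution of one spectrum for one class logit."""
    if results.task != "classify":
        raise ValueError("Grad-CAM requires a trained classification CNN")
    grid = x.grid if isinstance(x, Spectrum) else CANONICAL_GRID
    Z = results._features(x)                       # (1, p), normalised
    net = results.model.net
    tgt = results.model.cam_layer_index
    acts = net.forward_collect(Z[:, None, :], train=False)
    logits = acts[-1]
    n_classes = logits.shape[1]
    if not (0 <= class_id < n_classes):
        raise ValueError(f"class_id must be in [0, {n_classes - 1}]")
    dout = np.zeros_like(logits)
    dout[0, class_id] = 1.0
    dA = net.backward_from(tgt, dout)              # (1, C, L') grad wrt feature map
    A = acts[tgt]                                  # (1, C, L')
    alpha = dA.mean(axis=2)                        # (1, C) position-averaged grads
    cam = np.maximum((alpha[:, :, None] * A).sum(axis=1), 0.0)[0]   # (L',)
    # upsample the coarse map back onto the wavelength grid
    L = cam.size
    coarse = np.linspace(0.0, 1.0, L) if L > 1 else np.array([0.5])
    fine = np.linspace(0.0, 1.0, grid.n_points)
    imp = np.interp(fine, coarse, cam)
    peak = imp.max()
    if peak > 0:
        return AttributionCurve(grid, imp / peak, class_id, source)
    return AttributionCurve(grid, imp, class_id, source, all_zero=True)


def cam_for_class(results: CNNResults, dataset: SpectraSet, class_id: int
                  ) -> Union[AttributionCurve, CamRefusal]:
    """Class-average-spectrum attribution with the consistency check.

    Computes the mean spectrum of ``class_id``, classifies it, and returns
    its Grad-CAM only when the prediction matches; otherwise a
    :class:`CamRefusal` carrying the predicted class.
    """
    mean_spec = dataset.class_mean(class_id)
    pred = int(results.predict_classes(mean_spec.absorbance[None, :])[0])
    if pred != class_id:
        return CamRefusal(class_id=class_id, predicted_class=pred)
    curve = grad_cam(results, mean_spec, class_id, source="class_average")
    return curve
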