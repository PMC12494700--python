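"""scikit-learn-style estimator wrapping the full detector.

``GeneoPocketFinder`` follows the sklearn contract: hyperparameters are
constructor arguments stored verbatim, :meth:`fit` learns the 17 model
parameters from (channel stack, truth mask) pairs and exposes them as
trailing-underscore attributes, :meth:`predict` returns ranked pocket tables
and :meth:`score` the mean hard-threshold volumetric loss.  ``get_params`` /
``set_params`` come from :class:`sklearn.base.BaseEstimator`, so the finder
composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .channels import ChannelStack, TruthMask
from .kernels import DEFAULT_FAMILIES
from .model import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_SMALL_VOLUME,
    DEFAULT_VOLUME_REF,
    FreeKernelParams,
    GENEOParams,
    pockets_to_frame,
    run_model,
)
from .training import (
    TrainingConfig,
    TrainingExample,
    fit as _fit,
    mean_hard_loss,
)


def _as_examples(X, y) -> list[TrainingExample]:
    if y is None:
        raise ValueError("y (truth masks) is required")
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    out = []
    for stack, truth in zip(X, y):
        if not isinstance(stack, ChannelStack):
            raise TypeError("X entries must be ChannelStack objects")
        if isinstance(truth, TruthMask):
            tm = truth
        else:
            tm = TruthMask(grid=stack.grid, values=np.asarray(truth))
        out.append(TrainingExample(stack=stack, truth=tm))
    return out


class GeneoPocketFinder(BaseEstimator):
    """Volumetric pocket detector with a single equivariant operator layer.

    Parameters
    ----------
    variant : {"E-NE", "NE-NE", "NE-E"}
        Full model (equivariant + non-expansive) or one of the ablation
        variants with free kernels (L1-normalized or unconstrained).
    k : float
        Background weight of the volumetric loss, in [0, 1].
    epochs, learning_rate, random_state
        Optimization settings (per-example Adam, seeded shuffling).
    connectivity : {6, 18, 26}
        Voxel adjacency used for pocket labeling.
    volume_ref : float
        Volume scale (voxels) of the score adjustment
        ``mean_psi * (1 - exp(-V / volume_ref))``.
    small_volume : float
        Å^3 below which a pocket is flagged small.
    families : tuple of 8 str
        Kernel family per channel (E-NE variant).
    init_sigma, init_theta, temp_start, temp_end, truncation_factor
        Initialization and surrogate-annealing settings.

    Attributes
    ----------
    params_ : GENEOParams or FreeKernelParams
        Learned parameters after :meth:`fit`.
    sigmas_, alphas_, theta_ : learned parameter views (E-NE).
    train_loss_, val_loss_ : per-epoch hard-threshold loss histories.
    """

    def __init__(self, variant: str = "E-NE", k: float = 0.02,
                 epochs: int = 50, learning_rate: float = 0.01,
                 random_state: int = 0,
                 connectivity: int = DEFAULT_CONNECTIVITY,
                 volume_ref: float = DEFAULT_VOLUME_REF,
                 small_volume: float = DEFAULT_SMALL_VOLUME,
                 families: tuple = DEFAULT_FAMILIES,
                 init_sigma: float = 2.0, init_theta: float = 0.5,
                 temp_start: float = 0.1, temp_end: float = 0.01,
                 truncation_factor: float = 3.0):
        self.variant = variant
        self.k = k
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.connectivity = connectivity
        self.volume_ref = volume_ref
        self.small_volume = small_volume
        self.families = families
        self.init_sigma = init_sigma
        self.init_theta = init_theta
        self.temp_start = temp_start
        self.temp_end = temp_end
        self.truncation_factor = truncation_factor

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "GeneoPocketFinder":
        """Learn the model parameters from channel stacks and truth masks."""
        examples = _as_examples(X, y)
        val = _as_examples(X_val, y_val) if X_val is not None else None
        config = TrainingConfig(
            k=self.k, epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.random_state, temp_start=self.temp_start,
            temp_end=self.temp_end, init_sigma=self.init_sigma,
            init_theta=self.init_theta, families=tuple(self.families),
            truncation_factor=self.truncation_factor)
        result = _fit(examples, config, variant=self.variant,
                      val_examples=val)
        self._set_fitted(result.params)
        self.train_loss_ = result.train_loss
        self.val_loss_ = result.val_loss
        return self

    def _set_fitted(self, params) -> "GeneoPocketFinder":
        self.params_ = params
        if isinstance(params, GENEOParams):
            self.sigmas_ = params.sigmas
        self.alphas_ = params.alphas
        self.theta_ = params.theta
        self.n_parameters_ = (params.n_learnable
                              if isinstance(params, GENEOParams) else None)
        return self

    def with_params(self, params: GENEOParams | FreeKernelParams
                    ) -> "GeneoPocketFinder":
        """Install pre-trained parameters without fitting (e.g. loaded from
        JSON)."""
        return self._set_fitted(params)

    def predict(self, X, structures=None) -> list[pd.DataFrame]:
        """Ranked pocket table for each channel stack.

        ``structures`` optionally supplies the parameterized structures so
        HBA/HBD contact counts can be filled in.
        """
        check_is_fitted(self, "params_")
        single = isinstance(X, ChannelStack)
        stacks = [X] if single else list(X)
        structs = ([structures] if single else
                   list(structures) if structures is not None
                   else [None] * len(stacks))
        frames = [pockets_to_frame(self.forward(s, st).pockets)
                  for s, st in zip(stacks, structs)]
        return frames[0] if single else frames

    def forward(self, stack: ChannelStack, structure=None):
        """Full model output (fields, labels, pockets) for one stack."""
        check_is_fitted(self, "params_")
        return run_model(stack, self.params_, connectivity=self.connectivity,
                         volume_ref=self.volume_ref,
                         small_volume=self.small_volume, structure=structure)

    def score(self, X, y) -> float:
        """Mean hard-threshold volumetric loss (higher is better, max 1)."""
        check_is_fitted(self, "params_")
        return mean_hard_loss(self.params_, _as_examples(X, y), self.k)
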