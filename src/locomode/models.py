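"""Model/Results front door for locomotion-mode classification.

``LocomotionClassifier`` is constructed from a labeled window dataset (or
directly from recordings / a tidy DataFrame), holds the preprocessing and
training configuration, and ``fit()`` returns a
``LocomotionClassifierResults`` carrying the trained networks, their training
histories and evaluation methods, in the style of statistical modelling
packages where the model object is immutable data + configuration and the
results object owns the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data as _data
from .data import (
    Dataset,
    IMURecording,
    MinMaxNormalizer,
    MODES,
    extract_features,
    fit_normalizer,
    windows_from_recordings,
)
from .ibpnn import NetworkParams, TrainConfig, TrainHistory, forward_batch, init_params, train
from .abc_optimizer import ABCConfig, abc_init_network
from .dts import (
    DEFAULT_HIDDEN,
    DTSSpec,
    TrainedDTS,
    builtin_spec,
    predict_dts_batch,
    predict_flat_batch,
    train_dts,
)
from .evaluation import MetricsReport, count_params, evaluate_predictions

STRUCTURES = ("flat", "dts-a", "dts-b")


class LocomotionClassifier:
    """A locomotion-mode recognition model specification.

    Parameters
    ----------
    train : Dataset
        Labeled training windows (raw flattened samples or 24-dim features),
        *not* yet normalized; the model fits its own min-max normalizer.
    structure : {"flat", "dts-a", "dts-b"} or DTSSpec
        Flat 9-way network or a hierarchical decision-tree structure.
    hidden : int, optional
        Hidden-layer size for the flat network (default 100). Tree structures
        carry per-node sizes in their spec.
    train_config : TrainConfig, optional
    abc_config : ABCConfig, optional
        When given, initial weights/thresholds come from the artificial-bee-
        colony search instead of a plain uniform draw.
    """

    def __init__(
        self,
        train: Dataset,
        structure: str | DTSSpec = "dts-b",
        hidden: int = DEFAULT_HIDDEN,
        train_config: TrainConfig | None = None,
        abc_config: ABCConfig | None = None,
    ):
        if isinstance(structure, str):
            key = structure.lower()
            if key not in STRUCTURES:
                raise ValueError(f"structure must be one of {STRUCTURES} or a DTSSpec")
            self.spec = None if key == "flat" else builtin_spec(key)
            self.structure = key
        else:
            self.spec = structure
            self.structure = structure.name
        if len(train) == 0:
            raise ValueError("empty training dataset")
        self.train_data = train
        self.hidden = hidden
        self.train_config = train_config or TrainConfig()
        self.abc_config = abc_config

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[IMURecording],
        window_ms: int = 200,
        stride_ms: int | None = None,
        representation: str = "raw",
        **kwargs,
    ) -> "LocomotionClassifier":
        """Window a set of labeled recordings and build the model."""
        ds = windows_from_recordings(recordings, window_ms, stride_ms)
        if representation == "eigenvalues":
            ds = extract_features(ds)
        elif representation != "raw":
            raise ValueError("representation must be 'raw' or 'eigenvalues'")
        return cls(ds, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LocomotionClassifier":
        """Build from a tidy frame in the recording-CSV schema
        (subject_id, mode, t, ax..gz)."""
        import tempfile

        with tempfile.NamedTemporaryFile(suffix=".csv", mode="w", delete=False) as fh:
            df.to_csv(fh.name, index=False)
            recs = _data.read_recordings(fh.name)
        window_kw = {k: kwargs.pop(k) for k in ("window_ms", "stride_ms", "representation") if k in kwargs}
        return cls.from_recordings(recs, **window_kw, **kwargs)

    # -- estimation ----------------------------------------------------------

    def fit(self) -> "LocomotionClassifierResults":
        normalizer = fit_normalizer(self.train_data)
        norm_train = normalizer.transform(self.train_data)
        cfg = self.train_config
        if self.spec is None:
            flat = norm_train.with_flat_targets()
            arch = (flat.dim, self.hidden, len(MODES))
            if self.abc_config is not None:
                p0 = abc_init_network(flat, arch, self.abc_config, cfg)
            else:
                p0 = init_params(*arch, init_range=cfg.init_range, seed=cfg.seed)
            params, history = train(p0, flat, cfg)
            return LocomotionClassifierResults(
                model=self, normalizer=normalizer, flat_params=params, histories={"flat": history}
            )
        trained = train_dts(self.spec, norm_train, cfg, abc_cfg=self.abc_config)
        trained.normalizer = normalizer
        return LocomotionClassifierResults(
            model=self, normalizer=normalizer, tree=trained, histories=trained.histories
        )


@dataclass
class LocomotionClassifierResults:
    """Trained networks, training histories, and evaluation methods."""

    model: LocomotionClassifier
    normalizer: MinMaxNormalizer
    flat_params: NetworkParams | None = None
    tree: TrainedDTS | None = None
    histories: dict[str, TrainHistory] = field(default_factory=dict)

    # -- inference -----------------------------------------------------------

    def predict(self, ds_or_X) -> np.ndarray:
        """Mode labels for un-normalized windows (Dataset or raw matrix)."""
        ds = ds_or_X if isinstance(ds_or_X, Dataset) else Dataset(
            np.atleast_2d(np.asarray(ds_or_X, dtype=float)),
            np.array([MODES[0]] * np.atleast_2d(np.asarray(ds_or_X)).shape[0], dtype=object),
            self.model.train_data.window_ms,
        )
        X = self.normalizer.transform(ds).X
        if self.tree is not None:
            return predict_dts_batch(self.tree, X)
        return predict_flat_batch(self.flat_params, X)

    def scores(self, ds: Dataset) -> np.ndarray | None:
        """Per-class network outputs (flat structure only; tree routing has no
        single 9-way score vector)."""
        if self.flat_params is None:
            return None
        return forward_batch(self.flat_params, self.normalizer.transform(ds).X)

    def evaluate(self, test: Dataset) -> MetricsReport:
        pred = self.predict(test)
        return evaluate_predictions(test.labels, pred, MODES, scores=self.scores(test))

    # -- bookkeeping ---------------------------------------------------------

    @property
    def architectures(self) -> list[tuple[int, int, int]]:
        if self.tree is not None:
            return [
                (self.tree.params[nid].n, self.tree.params[nid].m, self.tree.params[nid].l)
                for nid in sorted(self.tree.spec.nodes)
            ]
        p = self.flat_params
        return [(p.n, p.m, p.l)]

    @property
    def n_parameters(self) -> int:
        return count_params(self.architectures).total

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.tree is not None:
            self.tree.normalizer = self.normalizer
            self.tree.save(directory)
        else:
            import json

            self.flat_params.save(directory / "flat.json")
            (directory / "normalizer.json").write_text(json.dumps(self.normalizer.to_dict()))

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        lines = []
        title = f"Locomotion-mode classifier [{self.model.structure}]"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"{'Structure:':<24}{self.model.structure}")
        lines.append(f"{'Training instances:':<24}{len(self.model.train_data)}")
        lines.append(f"{'Input dimension:':<24}{self.model.train_data.dim}")
        lines.append(f"{'Window length (ms):':<24}{self.model.train_data.window_ms}")
        lines.append(f"{'Total parameters:':<24}{self.n_parameters}")
        cfg = self.model.train_config
        lines.append(f"{'alpha0 / beta:':<24}{cfg.alpha0} / {cfg.beta}")
        lines.append(f"{'ABC initialization:':<24}{'yes' if self.model.abc_config else 'no'}")
        lines.append("-" * len(title))
        lines.append(f"{'network':<10}{'arch (n,m,l)':<18}{'params':>8}{'final err':>12}{'alpha_T':>10}")
        names = sorted(self.histories)
        for name, arch in zip(names, self.architectures):
            h = self.histories[name]
            n_par = count_params([arch]).total
            lines.append(
                f"{name:<10}{str(arch):<18}{n_par:>8}{h.epoch_error[-1]:>12.4f}{h.alpha[-1]:>10.4f}"
            )
        return "\n".join(lines)
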