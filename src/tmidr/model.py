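"""The compartment ensemble: four window CNNs plus a recurrent smoother.

Each non-membrane compartment (extracellular/intracellular x
distant/proximal) gets its own convolutional scorer over the 11 x 39 window
matrix; a truncated bidirectional recurrent network then refines the raw
per-residue track using the CNN score together with the compartment
encoding, looking 12 steps in each direction. Membrane residues always
carry a raw score of 0 and enter the smoother with a zeroed score input.

Estimators follow scikit-learn conventions (``fit``/``predict_score``,
``get_params``, fitted attributes with a trailing underscore) and the
high-level :class:`MembraneDisorderEnsemble` orchestrates dataset
construction, feature normalisation, training and prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from . import _nn
from .dataset import Fragment, select_fragments, split_fragments
from .features import (
    DEFAULT_SCHEMA,
    AccessibilityTrack,
    FeatureSchema,
    ProfileMatrix,
    feature_tensor_from_parts,
    pseudo_profile,
    seg_mask,
)
from .protein import DISORDERED, ORDERED, AnnotatedProtein
from .topology import (
    NON_MEMBRANE_CATEGORIES,
    Category,
    category_onehot,
    categorize,
)

#: Lookback of the bidirectional smoother, in residues per direction.
SMOOTHER_LOOKBACK = 12

#: Smoother input layout: raw score, 4 compartment bits, membrane bit.
SMOOTHER_INPUTS = 6


@dataclass
class TrainingConfig:
    """Optimisation settings shared by the CNNs and the smoother."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class CompartmentConvNet(BaseEstimator):
    """Convolutional scorer of one compartment's 11 x 39 windows.

    Two width-3 convolutions over the window axis (32 then 16 channels,
    ReLU), global average pooling and a dense sigmoid head; binary
    cross-entropy loss, Adam, early stopping with best-weight restoration.
    """

    def __init__(self, channels=(32, 16), kernel=3, lr=1e-3, batch_size=64,
                 max_epochs=150, patience=10, seed=0):
        self.channels = channels
        self.kernel = kernel
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, window, n_features)")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate(X)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(0.15 * len(y)))
            perm = rng.permutation(len(y))
            X_val, y_val = X[perm[:n_val]], y[perm[:n_val]]
            X, y = X[perm[n_val:]], y[perm[n_val:]]
        params = _nn.init_convnet(X.shape[1], X.shape[2], self.channels,
                                  self.kernel, rng)
        best, history = _nn.train_loop(
            params, _nn.convnet_forward, _nn.convnet_backward,
            X, y, self._validate(X_val), np.asarray(y_val, dtype=float),
            lr=self.lr, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, rng=rng,
        )
        self.params_ = best
        self.history_ = history
        self.best_epoch_ = int(np.argmin([v for _, v in history]))
        return self

    def predict_score(self, X) -> np.ndarray:
        """Disorder probability per window, in [0, 1]."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not trained")
        return _nn.convnet_forward(self.params_, self._validate(X), None)


class BiRNNSmoother(BaseEstimator):
    """Bidirectional recurrent refinement of a raw per-residue track.

    Each residue is scored from a window of ``lookback`` positions on either
    side: one tanh-RNN pass runs towards the residue from upstream, one from
    downstream, and their final hidden states feed a sigmoid head. By
    construction nothing outside the +/-``lookback`` window can influence a
    residue's output.
    """

    def __init__(self, hidden=8, lookback=SMOOTHER_LOOKBACK, lr=3e-3,
                 batch_size=256, max_epochs=40, patience=10, seed=0):
        self.hidden = hidden
        self.lookback = lookback
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _windows(self, inputs: np.ndarray) -> np.ndarray:
        """(L, d) track -> (L, 2*lookback+1, d) zero-padded windows."""
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim != 2:
            raise ValueError("smoother inputs must be (length, n_inputs)")
        T = self.lookback
        n, d = inputs.shape
        padded = np.zeros((n + 2 * T, d))
        padded[T : T + n] = inputs
        idx = np.arange(n)[:, None] + np.arange(2 * T + 1)[None, :]
        return padded[idx]

    def fit(self, tracks, labels, masks, val_fraction: float = 0.15):
        """Train on full-length fragment tracks.

        ``tracks`` is a list of (L_i, 6) input tracks; ``labels`` per-residue
        0/1 arrays; ``masks`` boolean arrays selecting the residues the loss
        is computed on (labelled, non-membrane). Membrane positions stay in
        the input windows with score 0.
        """
        rng = np.random.default_rng(self.seed)
        windows, ys = [], []
        for track, lab, mask in zip(tracks, labels, masks):
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                continue
            w = self._windows(track)
            windows.append(w[mask])
            ys.append(np.asarray(lab, dtype=float)[mask])
        if not windows:
            raise ValueError("no labelled residues to train on")
        X = np.concatenate(windows)
        y = np.concatenate(ys)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        n_val = max(1, int(val_fraction * len(y)))
        perm = rng.permutation(len(y))
        X_val, y_val = X[perm[:n_val]], y[perm[:n_val]]
        X_tr, y_tr = X[perm[n_val:]], y[perm[n_val:]]
        params = _nn.init_birnn(X.shape[2], self.hidden, self.lookback, rng)
        best, history = _nn.train_loop(
            params, _nn.birnn_forward, _nn.birnn_backward,
            X_tr, y_tr, X_val, y_val,
            lr=self.lr, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, rng=rng,
        )
        self.params_ = best
        self.history_ = history
        return self

    def predict_track(self, inputs) -> np.ndarray:
        """Refined per-residue scores for one (L, 6) input track."""
        if not hasattr(self, "params_"):
            raise RuntimeError("smoother is not trained")
        return _nn.birnn_forward(self.params_, self._windows(inputs), None)


def smoother_inputs(raw: np.ndarray, categories: np.ndarray) -> np.ndarray:
    """(L, 6) smoother input: zeroed-at-membrane score, compartment one-hot,
    membrane bit."""
    categories = np.asarray(categories)
    mem = categories == Category.MEMBRANE
    track = np.zeros((len(categories), SMOOTHER_INPUTS))
    track[:, 0] = np.where(mem, 0.0, np.asarray(raw, dtype=float))
    track[:, 1:5] = category_onehot(categories)
    track[:, 5] = mem.astype(float)
    return track


@dataclass
class EnsembleConfig:
    """Everything needed to build and train the full predictor."""

    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    cnn: TrainingConfig = field(default_factory=TrainingConfig)
    smoother: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(lr=3e-3, batch_size=256,
                                               max_epochs=40)
    )
    smoother_hidden: int = 8
    smoother_lookback: int = SMOOTHER_LOOKBACK
    split_ratios: tuple = (0.7, 0.15, 0.15)
    balance_tolerance: float = 0.10
    seed: int = 0


class MembraneDisorderEnsemble(BaseEstimator):
    """Four compartment CNNs + one bidirectional recurrent smoother."""

    def __init__(self, config: EnsembleConfig | None = None):
        self.config = config if config is not None else EnsembleConfig()

    # -- construction ------------------------------------------------------

    def build(self) -> "MembraneDisorderEnsemble":
        """Instantiate the 4 untrained CNNs and the untrained smoother."""
        cfg = self.config
        if cfg.schema.n_features != 39:
            raise ValueError("feature schema must have 39 columns")
        self.cnns_ = {}
        for i, cat in enumerate(NON_MEMBRANE_CATEGORIES):
            c = cfg.cnn
            self.cnns_[cat] = CompartmentConvNet(
                lr=c.lr, batch_size=c.batch_size, max_epochs=c.max_epochs,
                patience=c.patience, seed=cfg.seed * 1000 + i,
            )
        s = cfg.smoother
        self.smoother_ = BiRNNSmoother(
            hidden=cfg.smoother_hidden, lookback=cfg.smoother_lookback,
            lr=s.lr, batch_size=s.batch_size, max_epochs=s.max_epochs,
            patience=s.patience, seed=cfg.seed * 1000 + 99,
        )
        self.norm_mean_ = None
        self.norm_std_ = None
        self.schema_hash_ = cfg.schema.schema_hash()
        return self

    # -- featurisation -----------------------------------------------------

    def _fragment_parts(self, frag: Fragment, profiles: dict, rsas: dict):
        prof = profiles.get(frag.parent_id)
        if prof is None:
            prof = pseudo_profile(frag.sequence)
        else:
            prof = ProfileMatrix(prof.values[frag.start:frag.end], prof.source)
        rsa = rsas.get(frag.parent_id)
        if rsa is None:
            rsa = AccessibilityTrack.constant(len(frag))
        else:
            rsa = AccessibilityTrack(rsa.rsa[frag.start:frag.end], rsa.source)
        lc = seg_mask(frag.sequence)
        return prof, rsa, lc

    def _fragment_tensor(self, frag: Fragment, centers, profiles, rsas):
        prof, rsa, lc = self._fragment_parts(frag, profiles, rsas)
        return feature_tensor_from_parts(
            frag.sequence, frag.categories, prof, rsa, lc,
            np.asarray(centers), self.config.schema,
        )

    def _normalize(self, tensors: np.ndarray) -> np.ndarray:
        if self.norm_mean_ is None:
            return tensors
        out = tensors.copy()
        valid = out[:, :, 38] > 0
        normed = (out[:, :, :38] - self.norm_mean_) / self.norm_std_
        out[:, :, :38] = np.where(valid[:, :, None], normed, 0.0)
        return out

    def _fit_normalization(self, tensors: np.ndarray) -> None:
        """Per-feature z-statistics over valid rows of the training windows."""
        valid = tensors[:, :, 38] > 0
        rows = tensors[valid][:, :38]
        self.norm_mean_ = rows.mean(axis=0)
        std = rows.std(axis=0)
        self.norm_std_ = np.where(std > 1e-8, std, 1.0)

    # -- training ----------------------------------------------------------

    def fit(self, proteins, profiles=None, rsas=None):
        """End-to-end training from labelled proteins.

        Fragments are cut per protein, split with the identity guard,
        balanced per compartment, and used to train the four CNNs; the
        smoother is then trained on full-length fragment tracks. ``profiles``
        and ``rsas`` map protein id to :class:`ProfileMatrix` /
        :class:`AccessibilityTrack`; missing entries fall back to the
        substitution pseudo-profile and a constant accessibility.
        """
        profiles = profiles or {}
        rsas = rsas or {}
        cfg = self.config
        self.build()
        rng = np.random.default_rng(cfg.seed)

        fragments = []
        for protein in proteins:
            fragments.extend(select_fragments(protein, rng))
        if not fragments:
            raise ValueError("no fragments could be selected")
        split = split_fragments(fragments, cfg.split_ratios, seed=cfg.seed)
        self.fragments_ = fragments
        self.split_ = split

        train_idx = set(split.indices("train"))
        val_idx = set(split.indices("validation"))

        # featurise every fragment once (labelled non-membrane residues)
        tensors, labels, cats, owner = [], [], [], []
        for fi, frag in enumerate(fragments):
            if fi not in train_idx and fi not in val_idx:
                continue
            centers = [p for p in range(len(frag))
                       if frag.labels[p] in (DISORDERED, ORDERED)
                       and frag.categories[p] != Category.MEMBRANE]
            if not centers:
                continue
            t = self._fragment_tensor(frag, centers, profiles, rsas)
            tensors.append(t)
            labels.append(np.array(
                [1.0 if frag.labels[p] == DISORDERED else 0.0 for p in centers]))
            cats.append(frag.categories[centers])
            owner.append(np.full(len(centers), fi))
        X = np.concatenate(tensors)
        y = np.concatenate(labels)
        cat_arr = np.concatenate(cats)
        owner_arr = np.concatenate(owner)
        self._fit_normalization(X[np.isin(owner_arr, list(train_idx))])
        X = self._normalize(X)

        # per-compartment balanced training sets
        in_train = np.isin(owner_arr, list(train_idx))
        in_val = np.isin(owner_arr, list(val_idx))
        self.trained_categories_ = []
        for cat in NON_MEMBRANE_CATEGORIES:
            sel_tr = in_train & (cat_arr == cat)
            sel_va = in_val & (cat_arr == cat)
            idx_tr = self._balance_indices(np.where(sel_tr)[0], y, rng)
            if idx_tr is None or not sel_va.any() or \
                    len(np.unique(y[sel_va])) < 2:
                warnings.warn(
                    f"compartment {cat.name} lacks a usable train/validation "
                    "class balance; CNN not trained", stacklevel=2)
                continue
            self.cnns_[cat].fit(X[idx_tr], y[idx_tr], X[sel_va], y[sel_va])
            self.trained_categories_.append(cat)

        # smoother on full-length fragments (membrane included, loss masked)
        tracks, labs, masks = [], [], []
        for fi in sorted(train_idx | val_idx):
            frag = fragments[fi]
            raw = self._raw_scores_fragment(frag, profiles, rsas)
            tracks.append(smoother_inputs(raw, frag.categories))
            labs.append(np.array(
                [1.0 if c == DISORDERED else 0.0 for c in frag.labels]))
            masks.append(np.array(
                [c in (DISORDERED, ORDERED) for c in frag.labels])
                & (frag.categories != Category.MEMBRANE))
        self.smoother_.fit(tracks, labs, masks)
        return self

    def _balance_indices(self, idx: np.ndarray, y: np.ndarray,
                         rng: np.random.Generator):
        """Downsample the majority class of ``idx`` to the 10% tolerance."""
        tol = self.config.balance_tolerance
        pos = idx[y[idx] == 1.0]
        neg = idx[y[idx] == 0.0]
        if len(pos) == 0 or len(neg) == 0:
            return None
        minority = min(len(pos), len(neg))
        target = min(max(len(pos), len(neg)), int(np.floor(minority * (1 + tol))))
        if len(pos) > target:
            pos = rng.choice(pos, size=target, replace=False)
        if len(neg) > target:
            neg = rng.choice(neg, size=target, replace=False)
        out = np.concatenate([pos, neg])
        rng.shuffle(out)
        return out

    # -- prediction --------------------------------------------------------

    def _raw_from_tensor(self, tensors, categories) -> np.ndarray:
        """Route each residue's window to its compartment CNN; membrane -> 0."""
        categories = np.asarray(categories)
        raw = np.zeros(len(categories))
        tensors = self._normalize(tensors)
        for cat in NON_MEMBRANE_CATEGORIES:
            sel = categories == cat
            if not sel.any():
                continue
            cnn = self.cnns_[cat]
            if hasattr(cnn, "params_"):
                raw[sel] = cnn.predict_score(tensors[sel])
            else:
                raw[sel] = 0.5
        return raw

    def _raw_scores_fragment(self, frag, profiles, rsas) -> np.ndarray:
        tensors = self._fragment_tensor(frag, np.arange(len(frag)),
                                        profiles, rsas)
        return self._raw_from_tensor(tensors, frag.categories)

    def predict(self, protein: AnnotatedProtein,
                profile: ProfileMatrix | None = None,
                rsa: AccessibilityTrack | None = None,
                expected_schema_hash: str | None = None) -> dict:
        """Raw and refined per-residue tracks for one protein.

        Returns ``{"raw": ..., "refined": ..., "categories": ...}``;
        post-processing into the specific/sensitive modes lives in
        :mod:`tmidr.postprocess`.
        """
        if not hasattr(self, "cnns_"):
            raise RuntimeError("ensemble is not built/trained")
        if expected_schema_hash is not None and \
                expected_schema_hash != self.schema_hash_:
            raise ValueError("feature schema hash mismatch between input "
                             "pipeline and model artifact")
        if profile is None:
            profile = pseudo_profile(protein.sequence)
        if rsa is None:
            if protein.rsa is not None:
                rsa = AccessibilityTrack(protein.rsa)
            else:
                rsa = AccessibilityTrack.constant(len(protein))
        categories = categorize(protein.topology)
        lc = seg_mask(protein.sequence)
        tensors = feature_tensor_from_parts(
            protein.sequence, categories, profile, rsa, lc,
            np.arange(len(protein)), self.config.schema,
        )
        raw = self._raw_from_tensor(tensors, categories)
        refined = self.smoother_.predict_track(
            smoother_inputs(raw, categories))
        return {"raw": raw, "refined": refined, "categories": categories}

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write the model bundle: weights (npz) + YAML metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for cat in NON_MEMBRANE_CATEGORIES:
            cnn = self.cnns_[cat]
            if hasattr(cnn, "params_"):
                for k, v in cnn.params_.items():
                    arrays[f"cnn_{cat.name}_{k}"] = v
        if hasattr(self.smoother_, "params_"):
            for k, v in self.smoother_.params_.items():
                arrays[f"smoother_{k}"] = v
        if self.norm_mean_ is not None:
            arrays["norm_mean"] = self.norm_mean_
            arrays["norm_std"] = self.norm_std_
        np.savez(path / "weights.npz", **arrays)
        cfg = self.config
        meta = {
            "schema_hash": self.schema_hash_,
            "schema_version": cfg.schema.version,
            "schema_columns": list(cfg.schema.columns),
            "half_width": cfg.schema.half_width,
            "cnn": asdict(cfg.cnn),
            "smoother": asdict(cfg.smoother),
            "smoother_hidden": cfg.smoother_hidden,
            "smoother_lookback": cfg.smoother_lookback,
            "seed": cfg.seed,
            "trained_categories": [c.name for c in
                                   getattr(self, "trained_categories_", [])],
        }
        (path / "meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path) -> "MembraneDisorderEnsemble":
        path = Path(path)
        meta = yaml.safe_load((path / "meta.yaml").read_text())
        schema = FeatureSchema(half_width=meta["half_width"],
                               version=meta["schema_version"],
                               columns=tuple(meta["schema_columns"]))
        if schema.schema_hash() != meta["schema_hash"]:
            raise ValueError("schema hash in bundle does not match its columns")
        cfg = EnsembleConfig(
            schema=schema,
            cnn=TrainingConfig(**meta["cnn"]),
            smoother=TrainingConfig(**meta["smoother"]),
            smoother_hidden=meta["smoother_hidden"],
            smoother_lookback=meta["smoother_lookback"],
            seed=meta["seed"],
        )
        model = cls(cfg)
        model.build()
        data = np.load(path / "weights.npz")
        for cat in NON_MEMBRANE_CATEGORIES:
            prefix = f"cnn_{cat.name}_"
            params = {k[len(prefix):]: data[k] for k in data.files
                      if k.startswith(prefix)}
            if params:
                model.cnns_[cat].params_ = params
        sparams = {k[len("smoother_"):]: data[k] for k in data.files
                   if k.startswith("smoother_")}
        if sparams:
            model.smoother_.params_ = sparams
        if "norm_mean" in data.files:
            model.norm_mean_ = data["norm_mean"]
            model.norm_std_ = data["norm_std"]
        model.trained_categories_ = [Category[n] for n in
                                     meta["trained_categories"]]
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers


def build_ensemble(config: EnsembleConfig | None = None) -> MembraneDisorderEnsemble:
    """Untrained ensemble: exactly four compartment CNNs and one smoother."""
    return MembraneDisorderEnsemble(config).build()


def train_cnn(cnn: CompartmentConvNet, X, y, X_val, y_val):
    """Train one compartment CNN; returns (cnn, history)."""
    cnn.fit(X, y, X_val, y_val)
    return cnn, cnn.history_


def cnn_predict(ensemble: MembraneDisorderEnsemble, protein: AnnotatedProtein,
                **kw) -> np.ndarray:
    """Raw compartment-routed CNN track (membrane residues scored 0)."""
    return ensemble.predict(protein, **kw)["raw"]


def train_smoother(smoother: BiRNNSmoother, tracks, labels, masks):
    smoother.fit(tracks, labels, masks)
    return smoother


def smoother_predict(smoother: BiRNNSmoother, raw, categories) -> np.ndarray:
    """Refined track from a raw track and per-residue compartments."""
    raw = np.asarray(raw, dtype=float)
    categories = np.asarray(categories)
    if len(raw) != len(categories):
        raise ValueError("raw track and categories differ in length")
    return smoother.predict_track(smoother_inputs(raw, categories))


def composition_baseline(sequence: str, half_width: int = 5) -> np.ndarray:
    """Composition-only reference score: windowed mean disorder propensity,
    squashed to (0, 1). Used as the sanity baseline the ensemble must beat."""
    from .scales import DISORDER_PROPENSITY

    vals = np.array([DISORDER_PROPENSITY.get(aa, 0.0) for aa in sequence])
    kernel = np.ones(2 * half_width + 1)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(np.ones_like(vals), kernel, mode="same")
    return _nn.sigmoid(3.0 * num / den)
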