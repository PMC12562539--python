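"""Federated training engine: local updates, adaptive aggregation,
contrastive federated optimization, and multimodal fusion.

One training round (performed once per epoch) for the personalized
strategy:

1. **Local update** — every client runs one epoch of minibatch
   cross-entropy steps on its own data at the local rate ``alpha``; the GM
   head is fitted on the same batches (features detached from the encoder).
2. **Federated adaptive aggregation** — each client noises and broadcasts
   its GM head; peers return noised CE gradients of that head evaluated on
   their own locally encoded features; pair losses ``1 - cos`` become
   aggregation weights, and each client mixes the peers' noised parameter
   vectors into its own model, scaled by ``zeta``.
3. **Federated optimization** — one epoch on the composite loss
   ``L_cls + beta * L_GM + gamma * L_con`` at the federated rate ``eta``,
   where the contrastive term compares the current encoder's features with
   the locally updated and previous-round encoders on the same volumes.
4. **Fusion** — with all three modalities present, the per-client fusion
   MLP is trained on compact-bilinear-fused features while the
   single-modality models stay frozen.

Baselines: ``local`` (no communication), ``centralized`` (pooled data),
``fedavg`` (sample-size-weighted parameter averaging).  All cross-client
traffic — parameters and gradients alike — passes through the sender's
Gaussian mechanism; raw volumes and labels never cross a client boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .contrastive import ContrastiveConfig, contrastive_loss_and_grad
from .gradmatch import (adaptive_weights, gm_pair_loss, head_gradient,
                        head_hessian)
from .mcb import TrimodalSketchSpecs, fuse_trimodal, make_trimodal_specs
from .nets import (EncoderConfig, FusionMLP, ModalityModel, ModelState,
                   build_modality_model, flatten_params, unflatten_params)
from .privacy import NoiseConfig, gaussian_mechanism
from .synthetic import ClientData

__all__ = [
    "STRATEGIES",
    "MODALITIES",
    "FederatedConfig",
    "FederationData",
    "ClientSplit",
    "DivergenceError",
    "FederatedExperiment",
    "FederatedResults",
    "run_strategy",
    "local_update",
    "aggregate",
    "federated_optimize",
    "train_fusion_mlp",
    "evaluate",
    "federation_data_from_clients",
    "federation_data_from_manifest",
]

STRATEGIES = ("local", "centralized", "fedavg", "pf_gmco")
MODALITIES = ("smri", "alff", "reho")


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FederatedConfig:
    """Hyperparameters of one federated run.

    The full-scale profile uses 80 epochs, batch 8, alpha=0.01, eta=0.001,
    sigma2=0.001 with AdamW and the 1024-feature residual backbone; the
    desk-scale defaults below train the tiny CNN in CPU-minutes while
    keeping the local:federated learning-rate ratio.
    """

    epochs: int = 10
    alpha: float = 0.05            # local learning rate
    eta: float = 0.02              # federated learning rate
    zeta: float = 0.3              # aggregation strength
    beta: float = 1.0              # weight of the federated GM loss
    gamma: float = 1.0             # weight of the contrastive loss
    tau: float = 0.5               # contrastive temperature
    sigma2: float = 0.001          # Gaussian-mechanism variance
    batch_size: int = 8
    weight_mode: str = "similarity"            # or "as_printed"
    aggregation_mode: str = "convex"           # or "additive_as_printed"
    contrastive_variant: str = "as_printed"    # or "moon"
    adaptive_aggregation: bool = True
    gm_loss: bool = True
    contrastive: bool = True
    optimizer: str = "sgd"                     # or "adamw"
    weight_decay: float = 0.95                 # AdamW only
    encoder_variant: str = "tiny_cnn_3d"
    d_feat: int = 32
    mlp_hidden: int = 128
    modalities: tuple[str, ...] = MODALITIES
    fake_donor_noise: bool = False  # dishonest-federation robustness mode
    dtype: str = "float32"          # compute precision of the networks
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.eta < 0:
            raise ValueError("learning rates must be >= 0")
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def fusion(self) -> bool:
        return set(self.modalities) == set(MODALITIES)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ClientSplit:
    client_id: str
    train_volumes: dict[str, np.ndarray]
    train_labels: np.ndarray
    test_volumes: dict[str, np.ndarray]
    test_labels: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_labels)


@dataclass
class FederationData:
    clients: list[ClientSplit]

    def client_ids(self) -> list[str]:
        return [c.client_id for c in self.clients]


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Boolean test mask, stratified by label."""
    mask = np.zeros(len(labels), dtype=bool)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        rng.shuffle(idx)
        n_test = int(round(len(idx) * test_fraction))
        mask[idx[:n_test]] = True
    return mask


def federation_data_from_clients(clients: list[ClientData],
                                 test_fraction: float = 0.25,
                                 modalities: tuple[str, ...] = MODALITIES,
                                 seed: int = 0) -> FederationData:
    """Split in-memory synthetic clients into stratified train/test."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    splits = []
    for c in clients:
        labels = c.labels()
        test = _stratified_split(labels, test_fraction, rng)
        vols = {m: c.volumes(m) for m in modalities}
        splits.append(ClientSplit(
            client_id=c.client_id,
            train_volumes={m: v[~test] for m, v in vols.items()},
            train_labels=labels[~test],
            test_volumes={m: v[test] for m, v in vols.items()},
            test_labels=labels[test]))
    return FederationData(splits)


def federation_data_from_manifest(manifest, test_fold: int = 0,
                                  modalities: tuple[str, ...] = MODALITIES,
                                  ) -> FederationData:
    """Materialize a train/test federation from a manifest's fold column."""
    from .neuro_io import load_volume
    col = {"smri": "path_smri", "alff": "path_alff", "reho": "path_reho"}
    splits = []
    for cid in manifest.client_ids():
        rows = manifest.client_rows(cid)
        is_test = (rows["fold"] == test_fold).to_numpy()
        vols = {m: np.stack([load_volume(p) for p in rows[col[m]]])
                for m in modalities}
        labels = rows["label"].to_numpy()
        splits.append(ClientSplit(
            client_id=cid,
            train_volumes={m: v[~is_test] for m, v in vols.items()},
            train_labels=labels[~is_test],
            test_volumes={m: v[is_test] for m, v in vols.items()},
            test_labels=labels[is_test]))
    return FederationData(splits)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def _make_optimizer(named_params, lr: float, cfg: FederatedConfig | None):
    if cfg is not None and cfg.optimizer == "adamw":
        return nn.AdamW(named_params, lr, weight_decay=cfg.weight_decay)
    return nn.SGD(named_params, lr)


def _check_finite(loss: float, client: str, context: str) -> None:
    if not np.isfinite(loss):
        raise DivergenceError(f"non-finite loss for client {client!r} "
                              f"during {context}")


def local_update(model: ModalityModel, volumes: np.ndarray,
                 labels: np.ndarray, alpha: float,
                 batch_size: int = 8,
                 rng: np.random.Generator | None = None,
                 cfg: FederatedConfig | None = None,
                 client_id: str = "?", train_gm_head: bool = True) -> dict:
    """One epoch of minibatch CE steps on encoder+classifier.

    The GM head is fitted on the same batches; its loss does not
    backpropagate into the encoder.  Returns the mean losses of the epoch.
    """
    if len(labels) == 0:
        raise ValueError("local_update needs nonempty data")
    rng = rng or np.random.default_rng()
    order = rng.permutation(len(labels))
    opt = _make_optimizer(
        list(model.named_parameters(("encoder", "classifier"))), alpha, cfg)
    opt_gm = _make_optimizer(list(model.gm_head.named_parameters()), alpha, cfg)
    tot_cls, tot_gm, n_batches = 0.0, 0.0, 0
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        x, y = volumes[idx], labels[idx]
        opt.zero_grad()
        opt_gm.zero_grad()
        f = model.encode(x, train=True)
        logits = model.classifier(f, train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y)
        _check_finite(loss, client_id, "local update")
        df = model.classifier.backward(dlogits)
        model.encoder.backward(df)
        opt.step()
        if train_gm_head:
            gm_logits = model.gm_head(f, train=True)
            gm_loss, dgm = nn.softmax_cross_entropy(gm_logits, y)
            model.gm_head.backward(dgm)  # gradient w.r.t. f discarded
            opt_gm.step()
            tot_gm += gm_loss
        tot_cls += loss
        n_batches += 1
    return {"loss_cls": tot_cls / n_batches, "loss_gm_head": tot_gm / n_batches}


def aggregate(state_i: ModelState, noised_states: dict[object, np.ndarray],
              lam: dict[object, float], zeta: float,
              mode: str = "convex") -> ModelState:
    """Mix noised peer parameter vectors into a client's own state.

    ``additive_as_printed``: theta' = theta + zeta * sum lambda_j G(theta_j).
    ``convex``: theta' = (1-zeta) * theta + zeta * sum lambda_j G(theta_j),
    the bounded-norm default.
    """
    if mode not in ("convex", "additive_as_printed"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    v = flatten_params(state_i)
    if noised_states:
        total = sum(lam.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"aggregation weights sum to {total}, expected 1")
        mix = np.zeros_like(v)
        for cid, vec in noised_states.items():
            if vec.shape != v.shape:
                raise ValueError(f"peer {cid!r} parameter vector length "
                                 f"{vec.size} != {v.size}")
            mix += lam[cid] * vec
    else:
        mix = np.zeros_like(v)
        zeta = 0.0
    if mode == "additive_as_printed":
        out = v + zeta * mix
    else:
        out = (1 - zeta) * v + zeta * mix
    return unflatten_params(out, state_i)


def _gm_term(model: ModalityModel, features: np.ndarray, labels: np.ndarray,
             peer_grads: dict[object, np.ndarray]) -> tuple[float, np.ndarray]:
    """Federated GM loss on a batch and its gradient w.r.t. the GM head.

    ``g_i`` is the batch estimate of the local gradient expectation; peer
    gradients are the (noised, round-fixed) vectors from the exchange.  The
    dependence of ``g_i`` on the head parameters is differentiated exactly
    through the closed-form CE Hessian of the linear head; features are
    treated as constants.
    """
    wb = model.gm_head_matrix()
    g_i = head_gradient(wb, features, labels)
    ni = np.linalg.norm(g_i)
    if ni == 0:
        return 0.0, np.zeros_like(g_i)
    loss = 0.0
    dL_dgi = np.zeros_like(g_i)
    for g_j in peer_grads.values():
        nj = np.linalg.norm(g_j)
        if nj == 0:
            continue
        c = g_i @ g_j / (ni * nj)
        loss += 1.0 - c
        dL_dgi -= g_j / (ni * nj) - c * g_i / ni ** 2
    H = head_hessian(wb, features)
    return loss, H @ dL_dgi


def federated_optimize(model: ModalityModel, state_local: ModelState,
                       state_prev: ModelState, volumes: np.ndarray,
                       labels: np.ndarray,
                       peer_grads: dict[object, np.ndarray] | None,
                       cfg: FederatedConfig,
                       rng: np.random.Generator | None = None,
                       client_id: str = "?",
                       encoder_config: EncoderConfig | None = None) -> dict:
    """One epoch on the composite loss at the federated rate ``eta``.

    ``state_local`` is the state after this round's local update (source of
    f_local); ``state_prev`` is last round's final state (source of f_pre);
    the model itself currently holds the aggregated parameters.  Disabled
    terms contribute exactly zero and skip their computation entirely.
    """
    rng = rng or np.random.default_rng()
    use_gm = cfg.gm_loss and cfg.beta != 0 and bool(peer_grads)
    use_con = cfg.contrastive and cfg.gamma != 0
    enc_cfg = encoder_config or model.config

    f_local_all = f_pre_all = None
    if use_con:
        # frozen snapshots: their features are constants, computed once
        snap_local = build_modality_model(enc_cfg)
        snap_local.set_state(state_local)
        snap_prev = build_modality_model(enc_cfg)
        snap_prev.set_state(state_prev)
        f_local_all = snap_local.encode(volumes)
        f_pre_all = snap_prev.encode(volumes)
    ccfg = ContrastiveConfig(tau=cfg.tau, variant=cfg.contrastive_variant)

    order = rng.permutation(len(labels))
    opt = _make_optimizer(
        list(model.named_parameters(("encoder", "classifier"))), cfg.eta, cfg)
    opt_gm = _make_optimizer(list(model.gm_head.named_parameters()),
                             cfg.eta, cfg)
    log = {"loss_cls": 0.0, "loss_gm": 0.0, "loss_con": 0.0, "batches": []}
    n_batches = 0
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        x, y = volumes[idx], labels[idx]
        opt.zero_grad()
        opt_gm.zero_grad()
        f_fed = model.encode(x, train=True)
        logits = model.classifier(f_fed, train=True)
        loss_cls, dlogits = nn.softmax_cross_entropy(logits, y)
        _check_finite(loss_cls, client_id, "federated optimization")
        df = model.classifier.backward(dlogits)

        loss_con = 0.0
        if use_con:
            loss_con, dcon = contrastive_loss_and_grad(
                f_fed, f_local_all[idx], f_pre_all[idx], ccfg)
            df = df + cfg.gamma * dcon
        model.encoder.backward(df)
        opt.step()

        loss_gm = 0.0
        if use_gm:
            loss_gm, dwb = _gm_term(model, f_fed, y, peer_grads)
            wbmat = (cfg.beta * dwb).reshape(2, -1)
            model.gm_head.grads["W"] += wbmat[:, :-1]
            model.gm_head.grads["b"] += wbmat[:, -1]
            opt_gm.step()

        total = loss_cls + cfg.beta * loss_gm + cfg.gamma * loss_con
        log["batches"].append({"loss_cls": loss_cls, "loss_gm": loss_gm,
                               "loss_con": loss_con, "loss_total": total})
        log["loss_cls"] += loss_cls
        log["loss_gm"] += loss_gm
        log["loss_con"] += loss_con
        n_batches += 1
    for k in ("loss_cls", "loss_gm", "loss_con"):
        log[k] /= n_batches
    return log


def train_fusion_mlp(models: dict[str, ModalityModel], mlp: FusionMLP,
                     specs: TrimodalSketchSpecs,
                     volumes: dict[str, np.ndarray], labels: np.ndarray,
                     alpha: float, batch_size: int = 8,
                     rng: np.random.Generator | None = None,
                     epochs: int = 1,
                     cfg: FederatedConfig | None = None) -> dict:
    """Train the fusion MLP on fused features; modality models stay frozen."""
    rng = rng or np.random.default_rng()
    z = _fused_features(models, specs, volumes)
    opt = _make_optimizer(list(mlp.named_parameters()), alpha, cfg)
    tot, n_batches = 0.0, 0
    for _ in range(epochs):
        order = rng.permutation(len(labels))
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            logits = mlp.logits(z[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            _check_finite(loss, "fusion", "fusion MLP update")
            mlp.net.backward(dlogits)
            opt.step()
            tot += loss
            n_batches += 1
    return {"loss_mlp": tot / n_batches}


def _fused_features(models: dict[str, ModalityModel],
                    specs: TrimodalSketchSpecs,
                    volumes: dict[str, np.ndarray]) -> np.ndarray:
    f = {m: models[m].encode(volumes[m]) for m in MODALITIES}
    return fuse_trimodal(f["smri"], f["alff"], f["reho"], specs)


def evaluate(prob1: np.ndarray, labels: np.ndarray
             ) -> tuple[float, float | None]:
    """Accuracy (argmax at 0.5, i.e. class-1 probability >= 0.5 with
    index-order tie-break toward class 0) and ROC AUC (ties count half).

    AUC is ``None`` when only one class is present in ``labels``.
    """
    if len(labels) == 0:
        raise ValueError("empty evaluation split")
    pred = (np.asarray(prob1) > 0.5).astype(int)
    acc = float((pred == labels).mean())
    if len(np.unique(labels)) < 2:
        return acc, None
    return acc, float(roc_auc_score(labels, prob1))


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class _ClientRuntime:
    client_id: str
    models: dict[str, ModalityModel]
    mlp: FusionMLP | None
    specs: TrimodalSketchSpecs | None
    noise: NoiseConfig
    data_rng: np.random.Generator
    prev_states: dict[str, ModelState] = field(default_factory=dict)


class FederatedExperiment:
    """A federated training run, statsmodels-style: build, then ``fit()``.

    Parameters
    ----------
    data :
        ``FederationData`` (or a list of synthetic ``ClientData``, which is
        split 75/25 stratified by label).
    config :
        `FederatedConfig` hyperparameters.
    strategy :
        One of ``local``, ``centralized``, ``fedavg``, ``pf_gmco``.
    """

    def __init__(self, data, config: FederatedConfig = FederatedConfig(),
                 strategy: str = "pf_gmco", audit_exchanges: bool = False):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; "
                             f"expected one of {STRATEGIES}")
        if isinstance(data, list):
            data = federation_data_from_clients(
                data, modalities=config.modalities, seed=config.seed)
        if strategy in ("fedavg", "pf_gmco") and len(data.clients) < 2 \
                and strategy == "fedavg":
            raise ValueError("fedavg needs at least 2 clients")
        self.data = data
        self.config = config
        self.strategy = strategy
        self.audit_exchanges = audit_exchanges
        self.exchange_log: list[dict] = []

    @classmethod
    def from_manifest(cls, manifest_path, config: FederatedConfig,
                      strategy: str = "pf_gmco", test_fold: int = 0):
        from .neuro_io import load_manifest
        manifest = load_manifest(manifest_path)
        data = federation_data_from_manifest(
            manifest, test_fold=test_fold, modalities=config.modalities)
        return cls(data, config, strategy)

    # -- plumbing ----------------------------------------------------------
    def _init_clients(self) -> list[_ClientRuntime]:
        cfg = self.config
        runtimes = []
        # one shared initialization per modality: parameter averaging and
        # aggregation are only meaningful when clients share a starting point
        init_seeds = np.random.SeedSequence([cfg.seed, 11]).generate_state(
            len(cfg.modalities))
        for ci, split in enumerate(self.data.clients):
            ss = np.random.SeedSequence([cfg.seed, 7, ci])
            seeds = ss.generate_state(6)
            models = {}
            for mi, m in enumerate(cfg.modalities):
                shape = tuple(int(s) for s in
                              split.train_volumes[m].shape[1:])
                ec = EncoderConfig(variant=cfg.encoder_variant,
                                   d_feat=cfg.d_feat,
                                   seed=int(init_seeds[mi] % (2 ** 31)),
                                   input_shape=shape)
                models[m] = build_modality_model(ec).astype(cfg.dtype)
            mlp = specs = None
            if cfg.fusion:
                specs = make_trimodal_specs(cfg.d_feat, cfg.d_feat, cfg.d_feat,
                                            cfg.d_feat,
                                            seed=int(seeds[3] % (2 ** 31)))
                mlp = FusionMLP(cfg.d_feat, hidden=cfg.mlp_hidden,
                                seed=int(seeds[4] % (2 ** 31)))
            rt = _ClientRuntime(
                client_id=split.client_id, models=models, mlp=mlp,
                specs=specs,
                noise=NoiseConfig(cfg.sigma2, seed=int(seeds[5] % (2 ** 31))),
                data_rng=np.random.default_rng(ss.spawn(1)[0]))
            rt.prev_states = {m: models[m].state() for m in cfg.modalities}
            runtimes.append(rt)
        return runtimes

    def _share(self, vec: np.ndarray, sender: _ClientRuntime, kind: str,
               round_idx: int, fake_rng: np.random.Generator | None = None
               ) -> np.ndarray:
        """The only gate through which information leaves a client."""
        if self.config.fake_donor_noise:
            # dishonest client: plausible-scale random values instead of
            # the true message (scale-matched so the fake is not trivially
            # detectable by magnitude)
            scale = float(np.std(vec)) or 1.0
            out = (fake_rng or sender.data_rng).normal(
                0.0, scale, size=vec.shape).astype(vec.dtype)
        else:
            out = gaussian_mechanism(vec, sender.noise)
        if self.audit_exchanges:
            self.exchange_log.append({"round": round_idx,
                                      "sender": sender.client_id,
                                      "kind": kind, "shared": out,
                                      "raw": np.array(vec, copy=True)})
        return out

    def _encode_all(self, rt: _ClientRuntime, modality: str,
                    split: ClientSplit) -> tuple[np.ndarray, np.ndarray]:
        return (rt.models[modality].encode(split.train_volumes[modality]),
                split.train_labels)

    def _peer_gradient_exchange(self, recipient_vec: np.ndarray,
                                scratch: ModalityModel, recipient,
                                modality: str, round_idx: int,
                                kind: str) -> dict[str, np.ndarray]:
        """Peers evaluate the recipient's shared model on their own data.

        Each peer loads the recipient's noised parameter vector, encodes its
        own training volumes with that encoder, computes the mean CE
        gradient of the noised GM head on those features, and returns the
        gradient through its own Gaussian mechanism.  Using the *same*
        (recipient) model parameters for every peer makes the gradients a
        probe of data-distribution similarity.
        """
        template = scratch.state()
        scratch.set_state(unflatten_params(recipient_vec, template))
        wb = scratch.gm_head_matrix()
        peer_grads = {}
        for p, split in zip(self.clients_runtime, self.data.clients):
            if p is recipient:
                continue
            f = scratch.encode(split.train_volumes[modality])
            g = head_gradient(wb, f, split.train_labels)
            peer_grads[p.client_id] = self._share(
                g, p, f"{kind}:{modality}", round_idx)
        return peer_grads

    def _metrics(self, rt: _ClientRuntime, split: ClientSplit,
                 round_idx: int, records: list[dict]) -> None:
        cfg = self.config
        for part, vols, labels in (
                ("train", split.train_volumes, split.train_labels),
                ("test", split.test_volumes, split.test_labels)):
            for m in cfg.modalities:
                p = rt.models[m].predict_proba(vols[m])[:, 1]
                acc, auc = evaluate(p, labels)
                records.append({"round": round_idx, "client": rt.client_id,
                                "modality": m, "split": part, "acc": acc,
                                "auc": auc})
            if cfg.fusion:
                z = _fused_features(rt.models, rt.specs, vols)
                p = rt.mlp.predict_proba(z)[:, 1]
                acc, auc = evaluate(p, labels)
                records.append({"round": round_idx, "client": rt.client_id,
                                "modality": "fused", "split": part,
                                "acc": acc, "auc": auc})

    # -- strategies --------------------------------------------------------
    def fit(self) -> "FederatedResults":
        cfg = self.config
        runtimes = self._init_clients()
        self.clients_runtime = runtimes
        records: list[dict] = []
        weight_records: list[dict] = []
        losses: list[dict] = []

        for t in range(1, cfg.epochs + 1):
            if self.strategy == "centralized":
                self._round_centralized(runtimes, t, losses)
            elif self.strategy == "local":
                self._round_local(runtimes, t, losses)
            elif self.strategy == "fedavg":
                self._round_fedavg(runtimes, t, losses)
            else:
                self._round_pfgmco(runtimes, t, losses, weight_records)
            if cfg.fusion:
                for rt, split in zip(runtimes, self.data.clients):
                    train_fusion_mlp(rt.models, rt.mlp, rt.specs,
                                     split.train_volumes, split.train_labels,
                                     cfg.alpha, cfg.batch_size, rt.data_rng,
                                     cfg=cfg)
            for rt, split in zip(runtimes, self.data.clients):
                self._metrics(rt, split, t, records)

        return FederatedResults(
            strategy=self.strategy, config=cfg,
            round_log=pd.DataFrame.from_records(records),
            weight_log=pd.DataFrame.from_records(weight_records),
            loss_log=pd.DataFrame.from_records(losses),
            clients={rt.client_id: rt for rt in runtimes},
            exchange_log=self.exchange_log)

    def _round_local(self, runtimes, t, losses):
        cfg = self.config
        for rt, split in zip(runtimes, self.data.clients):
            for m in cfg.modalities:
                log = local_update(rt.models[m], split.train_volumes[m],
                                   split.train_labels, cfg.alpha,
                                   cfg.batch_size, rt.data_rng, cfg,
                                   rt.client_id)
                losses.append({"round": t, "client": rt.client_id,
                               "modality": m, **log})

    def _round_centralized(self, runtimes, t, losses):
        """All clients share one model trained on the pooled training set."""
        cfg = self.config
        lead = runtimes[0]
        for m in cfg.modalities:
            vols = np.concatenate([s.train_volumes[m]
                                   for s in self.data.clients])
            labels = np.concatenate([s.train_labels
                                     for s in self.data.clients])
            log = local_update(lead.models[m], vols, labels, cfg.alpha,
                               cfg.batch_size, lead.data_rng, cfg, "pooled")
            losses.append({"round": t, "client": "pooled", "modality": m,
                           **log})
            state = lead.models[m].state()
            for rt in runtimes[1:]:
                rt.models[m].set_state(state)

    def _round_fedavg(self, runtimes, t, losses):
        cfg = self.config
        self._round_local(runtimes, t, losses)
        n = np.array([s.n_train for s in self.data.clients], dtype=float)
        w = n / n.sum()
        for m in cfg.modalities:
            shared = [self._share(flatten_params(rt.models[m].state()), rt,
                                  f"params:{m}", t) for rt in runtimes]
            global_vec = sum(wi * v for wi, v in zip(w, shared))
            for rt in runtimes:
                rt.models[m].set_state(
                    unflatten_params(global_vec, rt.models[m].state()))

    def _round_pfgmco(self, runtimes, t, losses, weight_records):
        cfg = self.config
        # previous-round states feed f_pre during federated optimization
        pre_round_states = {rt.client_id: dict(rt.prev_states)
                            for rt in runtimes}
        self._round_local(runtimes, t, losses)
        if len(runtimes) == 1:
            # single client: no peers, the strategy degenerates to local
            runtimes[0].prev_states = {
                m: runtimes[0].models[m].state() for m in cfg.modalities}
            return

        for m in cfg.modalities:
            local_states = {rt.client_id: rt.models[m].state()
                            for rt in runtimes}
            # scratch model into which peers load a recipient's shared
            # (noised) parameters before encoding their own data with them
            scratch = build_modality_model(runtimes[0].models[m].config)

            # --- adaptive aggregation ---------------------------------
            shared_params = {rt.client_id: self._share(
                flatten_params(local_states[rt.client_id]), rt,
                f"params:{m}", t) for rt in runtimes}
            aggregated: dict[str, ModelState] = {}
            for rt, split in zip(runtimes, self.data.clients):
                peers = [p for p in runtimes if p is not rt]
                if cfg.adaptive_aggregation or cfg.gm_loss:
                    g_i = head_gradient(
                        rt.models[m].gm_head_matrix(),
                        *self._encode_all(rt, m, split))
                    peer_grads = self._peer_gradient_exchange(
                        shared_params[rt.client_id], scratch, rt, m, t,
                        "gm_grad")
                    pair = {cid: gm_pair_loss(g_i, g)
                            for cid, g in peer_grads.items()}
                else:
                    pair = {}
                if cfg.adaptive_aggregation and pair:
                    lam = adaptive_weights(pair, mode=cfg.weight_mode)
                else:
                    lam = {p.client_id: 1.0 / len(peers) for p in peers}
                for cid in lam:
                    weight_records.append({
                        "round": t, "modality": m,
                        "recipient": rt.client_id, "donor": cid,
                        "pair_loss": pair.get(cid, np.nan),
                        "lambda": lam[cid]})
                donor_vecs = {p.client_id: shared_params[p.client_id]
                              for p in peers}
                aggregated[rt.client_id] = aggregate(
                    local_states[rt.client_id], donor_vecs, lam, cfg.zeta,
                    cfg.aggregation_mode)

            # --- federated optimization -------------------------------
            # all clients adopt their aggregated parameters first, so the
            # second exchange evaluates peers at post-aggregation states
            for rt in runtimes:
                rt.models[m].set_state(aggregated[rt.client_id])
            for rt, split in zip(runtimes, self.data.clients):
                peer_grads = None
                if cfg.gm_loss and cfg.beta != 0:
                    shared_fed = self._share(
                        flatten_params(aggregated[rt.client_id]), rt,
                        f"params_fed:{m}", t)
                    peer_grads = self._peer_gradient_exchange(
                        shared_fed, scratch, rt, m, t, "gm_grad_fed")
                log = federated_optimize(
                    rt.models[m], local_states[rt.client_id],
                    pre_round_states[rt.client_id][m],
                    split.train_volumes[m], split.train_labels,
                    peer_grads, cfg, rt.data_rng, rt.client_id)
                losses.append({"round": t, "client": rt.client_id,
                               "modality": m, "phase": "federated",
                               "loss_cls": log["loss_cls"],
                               "loss_gm": log["loss_gm"],
                               "loss_con": log["loss_con"]})
        for rt in runtimes:
            rt.prev_states = {m: rt.models[m].state()
                              for m in cfg.modalities}


@dataclass
class FederatedResults:
    """Fit results: logs, per-client models, and summary statistics."""

    strategy: str
    config: FederatedConfig
    round_log: pd.DataFrame
    weight_log: pd.DataFrame
    loss_log: pd.DataFrame
    clients: dict[str, _ClientRuntime]
    exchange_log: list[dict]

    def final_metrics(self, split: str = "test") -> pd.DataFrame:
        df = self.round_log
        last = df["round"].max()
        return df[(df["round"] == last) & (df["split"] == split)]

    def mean_test_acc(self, modality: str | None = None) -> float:
        df = self.final_metrics("test")
        if modality is None:
            modality = "fused" if self.config.fusion else \
                self.config.modalities[0]
        return float(df[df["modality"] == modality]["acc"].mean())

    def summary(self) -> str:
        df = self.final_metrics("test")
        lines = [f"Federated run: strategy={self.strategy}, "
                 f"{len(self.clients)} clients, "
                 f"{self.config.epochs} rounds",
                 f"{'client':<12}{'modality':<10}{'ACC':>8}{'AUC':>8}"]
        for _, r in df.iterrows():
            auc = f"{r['auc']:.3f}" if pd.notna(r["auc"]) else "   --"
            lines.append(f"{r['client']:<12}{r['modality']:<10}"
                         f"{100 * r['acc']:>7.2f}%{auc:>8}")
        for m in sorted(df["modality"].unique()):
            sub = df[df["modality"] == m]
            lines.append(f"{'mean':<12}{m:<10}{100 * sub['acc'].mean():>7.2f}%"
                         f"{sub['auc'].mean():>8.3f}")
        return "\n".join(lines)


def run_strategy(strategy: str, data, config: FederatedConfig,
                 **kwargs) -> FederatedResults:
    """Functional wrapper over `FederatedExperiment`."""
    return FederatedExperiment(data, config, strategy, **kwargs).fit()
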