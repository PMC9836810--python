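"""Training objective: multilevel guidance loss, joint soft loss, trainer.

Prescriptions are weak-order sequences — the herbs matter, their order
barely does — so both output branches use a *soft* cross-entropy whose
target at step t is the average of the one-hot label for that step and
the bag of all label tokens scaled by 1/M:

    soft_t = (1/2) (q / M + onehot(y_t)),     L = -sum_t soft_t . log p_t.

The guidance branch adds a conventional per-step cross-entropy on top
(efficacy phrases *are* ordered), giving the multilevel guidance loss
with weights phi1 (soft) and phi2 (ordered).  The joint objective blends
the prescription branch and the guidance branch with weights psi1, psi2;
all four weights are learned through a homoscedastic-uncertainty
parameterisation w = exp(-rho) with a +rho regulariser, which keeps them
strictly positive.  The similarity gate folds into the guidance branch as
``guidance_scale * (1 - SC)``: supervision strengthens exactly when the
symptom and prescription representations disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .corpus import DataPair
from .layers import Adam
from .network import ForwardResult, TCMGenerator
from .tkmm import KnowledgeBase, build_kb

logger = logging.getLogger(__name__)

EPS = 1e-12

__all__ = ["LossBreakdown", "soft_cross_entropy", "loss_ckgm", "loss_final",
           "train", "TrainLog"]


@dataclass
class LossBreakdown:
    loss_ckgm: float
    loss_herb_soft: float
    loss_sim_gate: float
    phi1: float
    phi2: float
    psi1: float
    psi2: float
    total: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _log_dist(dist: Tensor, label_idx: int) -> Tensor:
    if dist.data[label_idx] < EPS:
        logger.warning("predicted probability underflow at label index %d; "
                       "clamped to %.0e", label_idx, EPS)
    return ad.log(dist, eps=EPS)


def soft_cross_entropy(dists: list[Tensor], label_ids: list[int],
                       vocab_size: int) -> Tensor:
    """Weak-order soft loss: -sum_t (1/2)(q/M + onehot(y_t)) . log p_t."""
    if len(dists) != len(label_ids):
        raise ValueError("one distribution per label step required")
    q = np.zeros(vocab_size)
    q[np.unique(label_ids)] = 1.0
    m = max(len(label_ids), 1)
    total = None
    for dist, y in zip(dists, label_ids):
        soft = q / (2.0 * m)
        soft = soft.copy()
        soft[y] += 0.5
        term = ad.neg(ad.tsum(ad.mul(Tensor(soft), _log_dist(dist, y))))
        total = term if total is None else ad.add(total, term)
    return total


def step_cross_entropy(dists: list[Tensor], label_ids: list[int]) -> Tensor:
    """Ordered per-step cross-entropy: -sum_t log p_t[y_t]."""
    total = None
    for dist, y in zip(dists, label_ids):
        term = ad.neg(_log_dist(dist, y)[y])
        total = term if total is None else ad.add(total, term)
    return total


def loss_ckgm(eff_dists: list[Tensor], eff_label_ids: list[int],
              eff_vocab_size: int, phi1, phi2) -> Tensor:
    """Multilevel guidance loss: phi1 * soft + phi2 * ordered CE."""
    term1 = soft_cross_entropy(eff_dists, eff_label_ids, eff_vocab_size)
    term2 = step_cross_entropy(eff_dists, eff_label_ids)
    return ad.add(ad.mul(phi1, term1), ad.mul(phi2, term2))


def loss_final(fwd: ForwardResult, network: TCMGenerator) -> tuple[Tensor, LossBreakdown]:
    """Joint objective for one pair; returns the scalar tensor and a
    detached numeric breakdown."""
    cfg = network.config
    if cfg.uncertainty_weighting:
        w = ad.exp(ad.neg(network.rho))
        psi1, psi2, phi1, phi2 = (w[i] for i in range(4))
        reg = ad.tsum(network.rho)
    else:
        psi1, psi2 = (Tensor(np.array(v)) for v in cfg.fixed_psi)
        phi1, phi2 = (Tensor(np.array(v)) for v in cfg.fixed_phi)
        reg = None

    herb_soft = soft_cross_entropy([s.p_final for s in fwd.step_states],
                                   fwd.herb_targets, len(network.vocab.herb))
    ckgm_branch = None
    gate_val = 0.0
    if fwd.eff_dists is not None:
        ckgm_branch = loss_ckgm(fwd.eff_dists, fwd.eff_targets,
                                len(network.vocab.efficacy), phi1, phi2)
        if fwd.gate is not None:
            gate_term = ad.mul(fwd.gate.guidance_scale,
                               ad.sub(1.0, fwd.gate.sc))
            gate_val = float(gate_term.data)
            ckgm_branch = ad.add(ckgm_branch, gate_term)

    total = ad.mul(psi1, herb_soft)
    if ckgm_branch is not None:
        total = ad.add(total, ad.mul(psi2, ckgm_branch))
    if reg is not None:
        total = ad.add(total, reg)

    bd = LossBreakdown(
        loss_ckgm=float(ckgm_branch.data) if ckgm_branch is not None else 0.0,
        loss_herb_soft=float(herb_soft.data),
        loss_sim_gate=gate_val,
        phi1=float(phi1.data), phi2=float(phi2.data),
        psi1=float(psi1.data), psi2=float(psi2.data),
        total=float(total.data))
    return total, bd


# ---------------------------------------------------------------------------
# training loop

@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_total: float = float("inf")
    best_state: dict | None = None
    aborted: bool = False
    kb: KnowledgeBase | None = None

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            if not self.epochs:
                return
            w = csv.DictWriter(fh, fieldnames=list(self.epochs[0]))
            w.writeheader()
            w.writerows(self.epochs)


def _refresh_kb_and_pools(network: TCMGenerator, pairs: list[DataPair]
                          ) -> tuple[KnowledgeBase, list[list[str] | None]]:
    kb = build_kb(pairs, network.represent)
    pools: list[list[str] | None] = []
    excl = network.config.kb_exclude_self
    for p in pairs:
        if not network.config.use_hcp or len(kb) < 2:
            pools.append(None)
            continue
        pool = network.retrieve(p.symptoms, kb,
                                exclude_source_id=p.source_id if excl else None)
        pools.append(pool.herbs)
    return kb, pools


def train(network: TCMGenerator, sp_pairs: list[DataPair],
          pe_pairs: list[DataPair] | None = None,
          config: ModelConfig | None = None,
          early_stop=None, eval_every: int = 10) -> TrainLog:
    """Teacher-forced joint training.

    The knowledge base is rebuilt from the training pairs with the current
    encoder every ``kb_refresh_epochs`` epochs; each pair's candidate pool
    excludes its own record so retrieval cannot leak the label.  The state
    with the lowest epoch-mean total loss is kept; a non-finite loss aborts
    the run with the last good state retained.  ``early_stop(epoch,
    network, kb)`` (checked every ``eval_every`` epochs) may end training
    early, e.g. once a memorisation target is reached.
    """
    cfg = config or network.config
    rng = np.random.default_rng(cfg.seed + 17)
    opt = Adam(network.parameters(), lr=cfg.lr, betas=cfg.betas, eps=cfg.adam_eps)
    log = TrainLog()

    if cfg.ckgm_pretrain_epochs > 0 and network.guidance is not None and pe_pairs:
        for _ in range(cfg.ckgm_pretrain_epochs):
            for p in pe_pairs:
                if not p.efficacy:
                    continue
                labels = (network.vocab.efficacy.encode(p.efficacy)
                          + [network.guidance.eos_id])
                dists, _ = network.guidance.teacher_forced(
                    network.vocab.herb.encode(p.prescription), labels)
                loss = loss_ckgm(dists, labels, len(network.vocab.efficacy),
                                 Tensor(np.array(1.0)), Tensor(np.array(1.0)))
                network.zero_grad()
                loss.backward()
                opt.step()

    kb, pools = _refresh_kb_and_pools(network, sp_pairs)
    for epoch in range(cfg.epochs):
        if epoch > 0 and cfg.kb_refresh_epochs > 0 and epoch % cfg.kb_refresh_epochs == 0:
            kb, pools = _refresh_kb_and_pools(network, sp_pairs)
        order = rng.permutation(len(sp_pairs))
        sums: dict[str, float] = {}
        n_since_step = 0
        network.zero_grad()
        diverged = False
        for j in order:
            fwd = network.forward_pair(sp_pairs[j], pools[j])
            total, bd = loss_final(fwd, network)
            if not np.isfinite(bd.total):
                diverged = True
                break
            ad.scale(total, 1.0 / cfg.batch_size).backward()
            for k, v in bd.as_dict().items():
                sums[k] = sums.get(k, 0.0) + v
            n_since_step += 1
            if n_since_step == cfg.batch_size:
                opt.step()
                network.zero_grad()
                n_since_step = 0
        if diverged:
            logger.error("non-finite loss at epoch %d; aborting with last good "
                         "state (epoch %d)", epoch, log.best_epoch)
            log.aborted = True
            break
        if n_since_step:
            opt.step()
            network.zero_grad()
        row = {k: v / len(sp_pairs) for k, v in sums.items()}
        row["epoch"] = epoch
        log.epochs.append(row)
        if row["total"] < log.best_total:
            log.best_total = row["total"]
            log.best_epoch = epoch
            log.best_state = network.state_dict()
        if early_stop is not None and (epoch + 1) % eval_every == 0:
            if early_stop(epoch, network, kb):
                break
    if log.best_state is not None:
        network.load_state_dict(log.best_state)
        kb, _ = _refresh_kb_and_pools(network, sp_pairs)
    log.kb = kb
    return log
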