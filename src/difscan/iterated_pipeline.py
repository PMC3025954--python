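"""Orchestration of the iterated profile strategy.

The flow: (1) bootstrap a training set inside the seed genus by
substitution-only fuzzy matching of the printed seed dif; (2) walk the
remaining genome groups in decreasing XerC/XerD similarity, scanning each
chromosome with the current profile, validating the best hit, folding
validated sites into the training set and re-checking the enlarged set by
leave-one-out cross-validation — additions that break LOOCV are evicted
from training but kept as predictions; (3) for genomes the main pass
leaves unresolved, a fallback cascade: class-level grouping, an
alternative seed profile built from the three closest trained genomes,
cross-group prediction with foreign profiles, and finally a relaxed mode
that reports palindrome- and position-consistent candidates as
provisional.  Every chromosome ends in exactly one terminal state:
validated, provisional, ambiguous or failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .genome_io import Chromosome
from .motif_profile import (MotifProfile, ScanHit, TrainingSite, build_profile,
                            loocv, scan)
from .phylo_order import (build_iteration_order, nearest_training_genomes,
                          organism_proteins, xercd_distance)
from .replication_stats import SkewReport, skew_report
from .seed_fuzzy import SeedDif, FuzzyHit, best_unique_hit, fuzzy_scan
from .site_validation import DifPrediction, palindrome_pairs, validate


@dataclass
class RunState:
    """Mutable state of one phylum run."""

    profile: MotifProfile | None = None
    training: list[TrainingSite] = field(default_factory=list)
    predictions: dict[str, DifPrediction] = field(default_factory=dict)
    audit: list[dict] = field(default_factory=list)

    def log(self, event: str, **details) -> None:
        self.audit.append({"event": event, **details})


@dataclass
class PhylumResult:
    predictions: dict[str, DifPrediction]       # chromosome id -> prediction
    profile: MotifProfile | None
    training: list[TrainingSite]
    skews: dict[str, SkewReport]
    audit: list[dict]


def _rebuild(state: RunState, config: PipelineConfig) -> None:
    state.profile = build_profile(
        [t.sequence for t in state.training],
        pseudocount=config.pseudocount,
        training_ids=[(t.genome_id, t.sequence) for t in state.training])


def bootstrap(genus_genomes: list[Chromosome], seed: SeedDif,
              config: PipelineConfig) -> tuple[RunState, list[Chromosome]]:
    """Fuzzy-match the seed dif across the seed genus; build the first profile.

    Per chromosome the single best hit enters training; chromosomes with
    tied best hits are recorded as ambiguous and excluded from the
    profile; chromosomes with no hit within ``max_substitutions`` are
    deferred to the fallback cascade.  Returns the state and the deferred
    chromosomes.
    """
    if not genus_genomes:
        raise ValueError("bootstrap requires at least one seed-genus genome")
    state = RunState()
    deferred: list[Chromosome] = []
    for chrom in sorted(genus_genomes, key=lambda c: c.id):
        hits = fuzzy_scan(chrom, seed, config.max_substitutions)
        best, ambiguous = best_unique_hit(hits)
        if best is None:
            state.log("bootstrap_no_hit", chromosome=chrom.id)
            deferred.append(chrom)
            continue
        if ambiguous:
            state.predictions[chrom.id] = DifPrediction(
                hit=best, organism=chrom.organism,
                palindrome_pairs=palindrome_pairs(best.matched),
                status="ambiguous", method="fuzzy",
                checks={"substitutions": best.substitutions, "ambiguous": True})
            state.log("bootstrap_ambiguous", chromosome=chrom.id,
                      substitutions=best.substitutions)
            continue
        state.training.append(TrainingSite(
            genome_id=chrom.organism, chromosome_id=chrom.id,
            start=best.start, strand=best.strand, sequence=best.matched))
        state.predictions[chrom.id] = DifPrediction(
            hit=best, organism=chrom.organism,
            palindrome_pairs=palindrome_pairs(best.matched),
            status="validated", method="fuzzy",
            checks={"substitutions": best.substitutions})
        state.log("bootstrap_hit", chromosome=chrom.id,
                  start=best.start, substitutions=best.substitutions)
    if not state.training:
        raise RuntimeError(f"bootstrap found no fuzzy hit for seed "
                           f"{seed.organism!r} in the seed genus")
    _rebuild(state, config)
    return state, deferred


def _loocv_gate(state: RunState, new_sites: list[TrainingSite],
                chromosomes: dict[str, Chromosome],
                config: PipelineConfig) -> None:
    """Run LOOCV on the enlarged training set; evict offending additions.

    New sites whose own held-out prediction fails are removed first; if
    older sites still fail, all of this round's additions are withdrawn.
    Evicted sites remain as predictions, flagged not-trained-on.
    """
    if len(state.training) < 2:
        state.log("loocv_skipped", reason="training size 1")
        return
    results = loocv(state.training, chromosomes,
                    score_threshold=config.score_threshold,
                    evalue_threshold=config.evalue_threshold,
                    pseudocount=config.pseudocount)
    failing = {gid for gid, ok in results.items() if not ok}
    if not failing:
        state.log("loocv_pass", size=len(state.training))
        return
    new_ids = {t.genome_id for t in new_sites}
    evict = failing & new_ids
    state.log("loocv_fail", failing=sorted(failing), evicting=sorted(evict))
    state.training = [t for t in state.training if t.genome_id not in evict]
    _rebuild(state, config)
    if len(state.training) >= 2:
        results = loocv(state.training, chromosomes,
                        score_threshold=config.score_threshold,
                        evalue_threshold=config.evalue_threshold,
                        pseudocount=config.pseudocount)
        still = {gid for gid, ok in results.items() if not ok}
        if still:
            evict2 = new_ids - evict
            state.log("loocv_fail_residual", failing=sorted(still),
                      evicting=sorted(evict2))
            state.training = [t for t in state.training
                              if t.genome_id not in evict2]
            _rebuild(state, config)
    for pred in state.predictions.values():
        if pred.organism in evict and pred.status == "validated":
            pred.checks["trained_on"] = False
    state.log("loocv_done", size=len(state.training))


def run_group_iteration(state: RunState, group: list[Chromosome],
                        chromosomes: dict[str, Chromosome],
                        skews: dict[str, SkewReport],
                        config: PipelineConfig,
                        method: str = "profile") -> list[Chromosome]:
    """Scan one genome group with the current profile and fold in results.

    Returns chromosomes left unresolved (rejected best hits) for the
    fallback cascade.
    """
    assert state.profile is not None
    unresolved: list[Chromosome] = []
    new_sites: list[TrainingSite] = []
    for chrom in group:
        hits = scan(state.profile, chrom)
        if not hits:
            unresolved.append(chrom)
            state.log("scan_empty", chromosome=chrom.id)
            continue
        pred = validate(hits[0], skews[chrom.id], config,
                        method=method, organism=chrom.organism)
        state.log("scan_best", chromosome=chrom.id, start=hits[0].start,
                  score=round(hits[0].bit_score, 3),
                  evalue=hits[0].e_value, status=pred.status)
        if pred.status == "validated":
            site = TrainingSite(genome_id=chrom.organism,
                                chromosome_id=chrom.id,
                                start=hits[0].start, strand=hits[0].strand,
                                sequence=hits[0].window)
            state.training.append(site)
            new_sites.append(site)
            state.predictions[chrom.id] = pred
        elif pred.status == "provisional":
            state.predictions[chrom.id] = pred
        else:
            unresolved.append(chrom)
    if new_sites:
        _rebuild(state, config)
        _loocv_gate(state, new_sites, chromosomes, config)
    return unresolved


def cross_group_predict(chrom: Chromosome, profiles: dict[str, MotifProfile],
                        skew: SkewReport, config: PipelineConfig,
                        organism: str = "") -> DifPrediction | None:
    """Predict with the final profiles of other groups.

    A candidate is accepted when at least two foreign profiles rank the
    identical genomic site best and it passes validation, or when a
    single profile's best hit attains full validated status; the best
    hit by bit score wins among validated candidates.  With no agreement
    and no validated single-profile hit, a site passing only palindrome
    and position is reported provisional.
    """
    if not profiles:
        return None
    best_by_profile: dict[str, ScanHit] = {}
    for label in sorted(profiles):
        hits = scan(profiles[label], chrom)
        if hits:
            best_by_profile[label] = hits[0]
    if not best_by_profile:
        return None
    # group identical sites (same start and strand)
    sites: dict[tuple[int, str], list[str]] = {}
    for label, hit in best_by_profile.items():
        sites.setdefault((hit.start, hit.strand), []).append(label)

    candidates: list[tuple[ScanHit, list[str], DifPrediction]] = []
    for (start, strand), labels in sorted(sites.items()):
        hit = max((best_by_profile[l] for l in labels), key=lambda h: h.bit_score)
        pred = validate(hit, skew, config, method="cross_group", organism=organism)
        if len(labels) >= 2 and pred.status in ("validated", "provisional"):
            candidates.append((hit, labels, pred))
        elif pred.status == "validated":
            candidates.append((hit, labels, pred))
    if candidates:
        hit, labels, pred = max(candidates, key=lambda c: c[0].bit_score)
        pred.checks["supporting_profiles"] = sorted(labels)
        return pred
    # provisional fallback: palindrome + position only
    provisional = [(best_by_profile[l], l) for l in sorted(best_by_profile)]
    for hit, label in sorted(provisional, key=lambda t: -t[0].bit_score):
        pred = validate(hit, skew, config, method="cross_group", organism=organism)
        if pred.status == "provisional":
            pred.checks["supporting_profiles"] = [label]
            return pred
    return None


def _relaxed_rescue(state: RunState, chrom: Chromosome,
                    skews: dict[str, SkewReport],
                    config: PipelineConfig) -> bool:
    """Last resort: best reported hit passing palindrome and position."""
    assert state.profile is not None
    for hit in scan(state.profile, chrom):
        pred = validate(hit, skews[chrom.id], config,
                        method="manual_relaxed", organism=chrom.organism)
        if pred.status in ("validated", "provisional"):
            pred.status = "provisional"
            state.predictions[chrom.id] = pred
            state.log("relaxed_rescue", chromosome=chrom.id, start=hit.start)
            return True
    return False


def run_phylum(genomes: list[Chromosome], seed: SeedDif, seed_organism: str,
               config: PipelineConfig,
               foreign_profiles: dict[str, MotifProfile] | None = None
               ) -> PhylumResult:
    """Full iterated run over one phylum (or class) of genomes.

    ``seed_organism`` anchors the iteration order; its genus is the
    bootstrap set.  ``foreign_profiles`` (final profiles of other phyla)
    power the cross-group fallback.
    """
    if not genomes:
        return PhylumResult({}, None, [], {}, [])
    chromosomes = {c.id: c for c in genomes}
    skews = {c.id: skew_report(c, gcsi_threshold=config.gcsi_threshold)
             for c in sorted(chromosomes.values(), key=lambda c: c.id)}

    order = build_iteration_order(genomes, seed_organism,
                                  group_by=config.group_by)
    by_organism: dict[str, list[Chromosome]] = {}
    for chrom in genomes:
        by_organism.setdefault(chrom.organism, []).append(chrom)

    seed_label = order.groups[0][0]
    seed_group_chroms = [c for _, members, _ in order.groups[:1]
                         for org in members for c in by_organism[org]]
    state, deferred = bootstrap(seed_group_chroms, seed, config)
    unresolved: list[Chromosome] = list(deferred)

    for label, members, distance in order.groups[1:]:
        if distance >= config.phylum_gap_warn:
            state.log("phylum_gap_warning", group=label,
                      distance=round(distance, 4))
        group_chroms = [c for org in members
                        for c in sorted(by_organism[org], key=lambda c: c.id)]
        unresolved += run_group_iteration(state, group_chroms, chromosomes,
                                          skews, config)
    # organisms excluded from the order (no XerC/XerD) terminate as failed
    ordered_orgs = {org for _, members, _ in order.groups for org in members}

    # ---- fallback cascade -------------------------------------------
    # (1) class-level regrouping: rebuild the iteration under the class
    # taxon and rescan unresolved genomes with profiles grown per class
    if unresolved and config.group_by == "genus":
        still: list[Chromosome] = []
        by_class: dict[str, list[TrainingSite]] = {}
        for site in state.training:
            chrom = chromosomes[site.chromosome_id]
            by_class.setdefault(chrom.klass, []).append(site)
        for chrom in unresolved:
            sites = by_class.get(chrom.klass, [])
            if len(sites) >= 2:
                class_profile = build_profile(
                    [s.sequence for s in sites], pseudocount=config.pseudocount)
                hits = scan(class_profile, chrom)
                if hits:
                    pred = validate(hits[0], skews[chrom.id], config,
                                    method="profile_class_level",
                                    organism=chrom.organism)
                    if pred.status == "validated":
                        state.predictions[chrom.id] = pred
                        state.log("class_level_rescue", chromosome=chrom.id)
                        continue
            still.append(chrom)
        unresolved = still

    # (2) alternative seed profile from the closest trained genomes
    if unresolved:
        proteins = organism_proteins(genomes)
        trained_orgs = {t.genome_id for t in state.training}
        trained_proteins = {o: proteins[o] for o in trained_orgs
                            if "xerC" in proteins.get(o, {}) and "xerD" in proteins.get(o, {})}
        sites_by_org: dict[str, list[TrainingSite]] = {}
        for site in state.training:
            sites_by_org.setdefault(site.genome_id, []).append(site)
        still = []
        for chrom in unresolved:
            target = proteins.get(chrom.organism, {})
            if ("xerC" in target and "xerD" in target
                    and len(trained_proteins) >= 2):
                nearest = nearest_training_genomes(
                    target, trained_proteins, k=config.alternative_seed_k)
                alt_training = [s.sequence for o in nearest
                                for s in sites_by_org[o]]
                alt_profile = build_profile(alt_training,
                                            pseudocount=config.pseudocount)
                hits = scan(alt_profile, chrom)
                if hits:
                    pred = validate(hits[0], skews[chrom.id], config,
                                    method="alternative_seed",
                                    organism=chrom.organism)
                    if pred.status == "validated":
                        state.predictions[chrom.id] = pred
                        state.log("alternative_seed_rescue",
                                  chromosome=chrom.id, nearest=nearest)
                        continue
            still.append(chrom)
        unresolved = still

    # (3) cross-group prediction with foreign final profiles
    if unresolved and foreign_profiles:
        still = []
        for chrom in unresolved:
            pred = cross_group_predict(chrom, foreign_profiles,
                                       skews[chrom.id], config,
                                       organism=chrom.organism)
            if pred is not None:
                state.predictions[chrom.id] = pred
                state.log("cross_group_rescue", chromosome=chrom.id,
                          profiles=pred.checks.get("supporting_profiles"))
            else:
                still.append(chrom)
        unresolved = still

    # (4) relaxed provisional mode; anything left is failed
    for chrom in unresolved:
        if not _relaxed_rescue(state, chrom, skews, config):
            best = scan(state.profile, chrom)[:1]
            state.predictions[chrom.id] = DifPrediction(
                hit=best[0] if best else _null_hit(chrom.id),
                organism=chrom.organism,
                palindrome_pairs=palindrome_pairs(best[0].window) if best else 0,
                status="failed", method="profile",
                checks={"reason": "no candidate passed any fallback"})
            state.log("failed", chromosome=chrom.id)
    for chrom in genomes:
        if chrom.organism not in ordered_orgs and chrom.id not in state.predictions:
            state.predictions[chrom.id] = DifPrediction(
                hit=_null_hit(chrom.id), organism=chrom.organism,
                status="failed", method="profile",
                checks={"reason": "organism lacks XerC/XerD"})

    return PhylumResult(predictions=dict(sorted(state.predictions.items())),
                        profile=state.profile, training=state.training,
                        skews=skews, audit=state.audit)


def _null_hit(chrom_id: str) -> ScanHit:
    return ScanHit(chrom_id, 1, "+", "N" * 28, float("-inf"), 1.0, float("inf"))
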