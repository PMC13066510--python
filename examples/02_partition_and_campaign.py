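"""Fingerprint-balanced partition plus a 4-generation active-learning campaign.

Participants are split into five intensity-balanced groups (Kruskal-Wallis
check on image fingerprints), roles are assigned (initial training, fixed
validation, per-generation pool waves, hold-out), and an uncertainty-driven
campaign runs: each generation scores the candidate pool by median voxel
entropy, selects images above mean + 1 SD, labels new ones once, and adds an
extra training copy for re-selected ones.  Run time: a few seconds on the
small demonstration cohort.
"""

from airway4d import SyntheticCohort, assign_roles, cohort_fingerprints, partition_cohort
from airway4d.pipeline import campaign_on_cohort
from airway4d.cohort import DEFAULT_EFFECTS, CohortConfig

# small cohort so the reference backend refits in seconds
effects = {m: dict(t) for m, t in DEFAULT_EFFECTS.items()}
effects["total_length_cm"].update(intercept=4.0, male=0.5, symptomatic=0.4,
                                  open=0.3, participant_sd=0.25, position_sd=0.08)
config = CohortConfig(n_participants=10, n_frames_per_position=2,
                      grid_shape=(32, 32, 48), sex_counts=(5, 5),
                      n_osa_excluded=0, symptomatic_fraction=0.5,
                      effect_table=effects, seed=3)
cohort = SyntheticCohort(config)

plan = partition_cohort(cohort_fingerprints(cohort), seed=3)
print(f"partition balance: Kruskal-Wallis p = {plan.balance_p:.3f} "
      f"after {plan.n_attempts} attempt(s)")

plan = assign_roles(plan, seed=3, n_initial_train=1, n_fixed_validation=1)
for role in sorted(set(plan.roles.values())):
    print(f"  {role:>16}: {plan.role_members(role)}")

state = campaign_on_cohort(cohort, plan, seed=3)
state.check_isolation()   # validation/hold-out images never entered training

print("\ngen  thr    new  resel  total  unique  val_dice  pool_entropy")
for g in state.selection_log:
    thr = f"{g.threshold:.3f}" if g.threshold == g.threshold else "  -  "
    print(f"{g.generation:>3}  {thr}  {g.n_new:>3}  {g.n_reselected:>5}  "
          f"{g.training_total:>5}  {g.training_unique:>6}  {g.val_dice_mean:>8.3f}"
          f"  {g.pool_entropy_median:>12.4f}")

print("\ntraining multiset (image: copies):")
for iid, mult in sorted(state.training.items()):
    print(f"  {iid}: {mult}")
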