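# Tailoring configuration: harm ranking, target-drug eligibility,
# stage-matched change-process modules, goal menus, and per-drug risk
# education bullets.  Everything here is editable; code never hard-codes
# these choices.

# Tie-breaker order, highest perceived harm first.  Only the endpoints
# are fixed by design (opioids at the top, cannabis at the bottom); the
# middle is an editable default.
ranking:
  - opioids
  - stimulants
  - cocaine
  - sedatives
  - inhalants
  - hallucinogens
  - tobacco
  - alcohol
  - cannabis

# Substances a session may target.  Tobacco and alcohol are screened and
# charted but not targeted by default.
eligible:
  - cannabis
  - cocaine
  - stimulants
  - inhalants
  - sedatives
  - hallucinogens
  - opioids

# Exactly three change-process modules per (purpose, stage).
stage_modules:
  quit:
    precontemplation: [pros_of_change, consciousness_raising, dramatic_relief]
    contemplation: [pros_of_change, self_reevaluation, environmental_reevaluation]
    preparation: [self_liberation, helping_relationships, small_steps]
    action: [counterconditioning, reinforcement_management, stimulus_control]
    maintenance: [relapse_prevention, stimulus_control, helping_relationships]
  seek_treatment:
    precontemplation: [pros_of_treatment, consciousness_raising, dramatic_relief]
    contemplation: [pros_of_treatment, treatment_options, self_reevaluation]
    preparation: [warm_handoff, appointment_planning, helping_relationships]
    action: [appointment_keeping, reinforcement_management, helping_relationships]
    maintenance: [relapse_prevention, helping_relationships, stimulus_control]

# Stage-matched goal menus the patient chooses from.
goal_menus:
  quit:
    precontemplation: [learn_one_risk_fact, track_my_use, talk_to_someone_i_trust]
    contemplation: [list_my_pros, picture_my_future_self, pick_a_change_date_window]
    preparation: [set_a_quit_date, tell_a_support_person, remove_triggers_at_home]
    action: [avoid_one_risky_place, swap_in_a_healthy_habit, reward_a_clean_week]
    maintenance: [plan_for_slips, keep_one_support_routine, help_someone_else]
  seek_treatment:
    precontemplation: [read_about_treatment, note_what_gets_in_the_way]
    contemplation: [compare_two_treatment_options, ask_provider_one_question]
    preparation: [call_agency_with_provider, set_first_appointment]
    action: [keep_my_next_appointment, plan_the_trip_there]
    maintenance: [stay_with_my_program, plan_for_hard_days]

# Risk-education bullets shown for the target drug.
drug_risks:
  cannabis:
    - Regular use can harm memory and focus.
    - Smoke can hurt your lungs.
  cocaine:
    - Use can cause heart attack and stroke.
    - Strong cravings make it hard to stop.
  stimulants:
    - Use can cause a fast heart beat and panic.
    - Sleep loss and weight loss are common harms.
  inhalants:
    - Fumes can hurt your brain and liver.
    - One deep breath can stop the heart.
  sedatives:
    - Mixing with other drugs can stop your breathing.
    - Your body can come to depend on them.
  hallucinogens:
    - Use can bring fear, panic, and risky acts.
    - Flashbacks can come back weeks later.
  opioids:
    - Overdose can stop your breathing.
    - Your body can come to depend on them fast.
  tobacco:
    - Smoking causes cancer and heart disease.
  alcohol:
    - Heavy drinking harms the liver and heart.
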