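# Acceptability instruments (5-point Likert, 1 = strongly disagree to
# 5 = strongly agree) and reference item-level statistics from the pilot
# evaluation.  `reference_means` are the published per-item mean ratings
# used as regression benchmarks; `n` is the number of respondents.
benchmark: 4.0
instruments:
  provider_dashboard:
    n: 3
    items:
      - id: easy_to_use
        text: The program was easy to use
        reference_mean: 4.3
      - id: data_easy_to_understand
        text: The data were easy to understand
        reference_mean: 4.7
      - id: liked_the_look
        text: I like the way the program looked
        reference_mean: 4.3
      - id: could_help_patient_change
        text: The program could help my patient make some positive changes
        reference_mean: 3.7
      - id: helpful_information_about_patient
        text: The program can give me helpful information about my patient
        reference_mean: 5.0
      - id: willing_to_use_again
        text: I would be willing to use this program again
        reference_mean: 4.3
  patient_session:
    n: 4
    items:
      - id: easy_to_use
        text: The program was easy to use
        reference_mean: 5.0
      - id: questions_easy_to_understand
        text: The questions were easy to understand
        reference_mean: 4.8
      - id: feedback_easy_to_understand
        text: The personal feedback was easy to understand
        reference_mean: 4.5
      - id: liked_the_look
        text: I like the way the program looked
        reference_mean: 4.3
      - id: respected_my_views
        text: I felt the program respected my thoughts and point of view
        reference_mean: 4.0
      - id: new_things_to_think_about
        text: The program gave me new things to think about
        reference_mean: 4.5
      - id: could_help_me_change
        text: The program could help me make some positive changes
        reference_mean: 4.5
      - id: helpful_information_for_provider
        text: The program can give my provider helpful information about me
        reference_mean: 4.5
      - id: willing_to_use_again
        text: I would be willing to use this program again
        reference_mean: 4.5
      - id: know_someone_who_could_benefit
        text: I know someone else who could benefit from this program
        reference_mean: 4.3
  text_messages:
    n: 4
    items:
      - id: easy_to_understand
        text: The text messages were easy to understand
        reference_mean: 3.6
      - id: reinforced_session
        text: The text messages reinforced things I learned in the online session
        reference_mean: 4.1
      - id: supportive
        text: The text messages were supportive
        reference_mean: 3.8
      - id: new_things_to_think_about
        text: The text messages gave me new things to think about
        reference_mean: 4.5
      - id: could_help_me_change
        text: The text messages could help me make some positive changes
        reference_mean: 3.6
      - id: worth_the_time
        text: Reading the text messages was worth the time it took
        reference_mean: 4.8
      - id: good_arrival_times
        text: The text messages arrived at times when it was good for me to receive them
        reference_mean: 4.0
      - id: know_someone_who_could_benefit
        text: I know someone else who could benefit from messages like these
        reference_mean: 3.7
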