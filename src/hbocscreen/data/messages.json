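{
  "greeting": "Hello! My name is {persona_name}, a {persona_occupation}. {persona_greeting} I will ask you about your family and your medical history; your preliminary screening result will appear at the end. ",
  "proband_sex": "First, what is your sex?",
  "proband_age": "How old are you? (Enter your age in years.)",
  "member_alive": "Is {relation} alive or deceased?",
  "member_age": "What is the age of {relation}? (Current age if alive, age at death if deceased; type 'unknown' if you do not know.)",
  "member_sex": "Is {relation} female or male?",
  "count_uncles_aunts_paternal": "How many brothers and sisters does your father have? (Your paternal uncles and aunts; enter 0 if none.)",
  "count_uncles_aunts_maternal": "How many brothers and sisters does your mother have? (Your maternal uncles and aunts; enter 0 if none.)",
  "count_cousins": "How many children does {relation} have? (Enter 0 if none.)",
  "count_siblings": "How many brothers and sisters do you have? (Enter 0 if none.)",
  "count_children": "How many children do you have? (Enter 0 if none.)",
  "count_nieces_nephews": "How many children does {relation} have? (Enter 0 if none.)",
  "cancer_any_self": "Now about medical history. Have you ever been diagnosed with cancer?",
  "cancer_any_member": "Has {relation} ever been diagnosed with cancer?",
  "cancer_site_self": "What type of cancer were you diagnosed with?",
  "cancer_site_member": "What type of cancer was {relation} diagnosed with?",
  "cancer_age_self": "At what age were you diagnosed? (Type 'unknown' if you do not know.)",
  "cancer_age_member": "At what age was {relation} diagnosed? (Type 'unknown' if you do not know.)",
  "cancer_more_self": "Have you been diagnosed with any other cancer?",
  "cancer_more_member": "Has {relation} been diagnosed with any other cancer?",
  "closing": "Thank you. That is everything I need; your screening result is ready.",
  "clarify_age": "Sorry, I did not understand. Please enter an age between 0 and 130, or type 'unknown'.",
  "clarify_count": "Sorry, I did not understand. Please enter a whole number between 0 and 12.",
  "clarify_yesno": "Sorry, I did not understand. Please answer 'yes' or 'no'.",
  "clarify_choice": "Sorry, I did not understand. Please answer with one of the numbered options, by number or by name.",
  "suspended": "I am having trouble understanding. Let me call a staff member to assist you."
}
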