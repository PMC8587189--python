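label,k,n,printed_percent
participants_male,9,18,50
participants_female,9,18,50
completed_fellowship,14,18,78
experience_up_to_15_years,13,18,72
survey_response_rate,18,65,28
smooth_navigation,7,18,39
help_dialogs_useful,3,6,50
help_dialogs_no_preference,1,6,17
approved_pie_charts,17,18,94
pie_chart_tap_reservations,7,15,47
chart_overlap_glitch,5,18,28
proposed_quick_edit_menu,2,18,11
liked_pie_chart_content,9,11,82
liked_delayed_transplant_feature,11,13,85
requested_gvhd_severity_grades,4,18,22
requested_gvhd_prophylaxis_info,6,18,33
requested_comorbidity_index,5,18,28
would_use_in_patient_consults,13,15,87
reservations_about_consult_use,2,18,11
tool_would_ease_decision_making,8,9,89
simplify_terminology_for_patients,9,12,75
decision_aid_before_consultation,3,6,50
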