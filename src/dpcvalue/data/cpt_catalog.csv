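code_key,description,allocation,work_rvu,payable_commercial,payable_medicare,payable_medicaid,per_visit
office_visit,Physician office visit,1.0,1.9200000000000002,payable,payable,payable,true
hba1c_test,Hemoglobin A1c level,1.0,,payable,payable,payable,true
urinalysis,Urinalysis,1.0,,bundled,bundled,bundled,true
lipid_panel,Lipid panel,0.44,,payable,payable,payable,true
cbc_auto_diff,Complete blood count with auto-differential,1.0,,payable,payable,payable,true
bp_setup_education,Education on self-managed blood pressure setup,0.68,0.179946949602122,payable,payable,payable,true
bp_monitor_education,Education on self-managed blood pressure monitor,0.68,0.23992705570291778,payable,payable,not_covered,true
tobacco_cessation,Tobacco cessation,0.22,0.23987704918032787,payable,payable,payable,true
foot_exam,Diabetic foot examination,1.0,,bundled,bundled,bundled,true
depression_screen,Depression,0.25,,payable,payable,payable,true
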