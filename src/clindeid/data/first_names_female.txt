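Sofía
Emilia
Isidora
Antonia
Florencia
Valentina
Martina
Catalina
Fernanda
Francisca
Javiera
Constanza
Camila
María
Josefa
Amanda
Maite
Trinidad
Agustina
Isabella
Monserrat
Rafaela
Laura
Julieta
Emma
Olivia
Matilde
Leonor
Gabriela
Daniela
Carolina
Paula
Andrea
Claudia
Marcela
Paulina
Alejandra
Verónica
Patricia
Carmen
Rosa
Elena
Teresa
Cecilia
Lorena
Sandra
Mónica
Angélica
Pamela
Ximena
Karen
Evelyn
Macarena
Tamara
Nicole
Bárbara
Romina
Natalia
Viviana
Ingrid
Jacqueline
Marisol
Pilar
Soledad
Magdalena
Rocío
Consuelo
Amparo
Victoria
Ignacia
Colomba
Renata
Dominga
Pascuala
Esperanza
Aurora
Margarita
Beatriz
Gloria
Silvia
Norma
Inés
Raquel
Susana
Adriana
Liliana
Miriam
Ruth
Gladys
Eliana
Berta
Luz
Nancy
Olga
Irma
Edith
Hilda
Elsa
Yasna
Millaray
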